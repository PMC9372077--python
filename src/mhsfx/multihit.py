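"""Detection of crystals hit by consecutive XFEL pulses (double hits).

A crystal drifting with the liquid jet can sit inside the X-ray focus for
more than one pulse of a MHz pulse train.  Its two indexing solutions then
share (almost) the same orientation, because the crystal tumbles only a
little in the sub-microsecond between pulses, while unrelated crystals
arrive with uniformly random orientations.  The classifier therefore pairs
crystals on *adjacent pulses of the same train* whose reciprocal bases agree
vector-by-vector: every inter-vector angle below ``max_angle`` (default 5
degrees) and every length ratio within ``max_length_frac`` (default 10%).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .stream_io import IndexedCrystal, StreamDataset

__all__ = [
    "MultiHitCriteria",
    "OrientationChange",
    "HitLabel",
    "RunSummary",
    "ClassificationResult",
    "OrientationHistogram",
    "orientation_change",
    "classify",
    "orientation_histogram",
    "summarize",
    "split",
]


@dataclass(frozen=True)
class MultiHitCriteria:
    """Matching thresholds for declaring two indexing solutions one crystal."""

    max_angle: float = 5.0           # degrees, per basis vector
    max_length_frac: float = 0.10    # fractional length agreement
    require_same_train: bool = True
    require_adjacent_pulse: bool = True

    def __post_init__(self):
        if not 0 < self.max_angle < 180:
            raise ValueError("max_angle must lie in (0, 180) degrees")
        if not 0 < self.max_length_frac < 1:
            raise ValueError("max_length_frac must lie in (0, 1)")


@dataclass(frozen=True)
class OrientationChange:
    """Per-vector rotation angles and length ratios between two bases."""

    angle_a: float
    angle_b: float
    angle_c: float
    ratio_a: float
    ratio_b: float
    ratio_c: float

    @property
    def summary_angle(self) -> float:
        """Largest of the three vector angles (all must pass the cut)."""
        return max(self.angle_a, self.angle_b, self.angle_c)

    def passes(self, criteria: MultiHitCriteria) -> bool:
        lo, hi = 1 - criteria.max_length_frac, 1 + criteria.max_length_frac
        return (self.summary_angle < criteria.max_angle
                and all(lo <= r <= hi
                        for r in (self.ratio_a, self.ratio_b, self.ratio_c)))


class HitLabel(enum.Enum):
    SINGLE = "single"
    FIRST = "first"
    SECOND = "second"
    RUN_EXTRA = "run_extra"   # third or later frame of a chain


def orientation_change(earlier: IndexedCrystal,
                       later: IndexedCrystal) -> OrientationChange:
    """Angles/ratios between corresponding reciprocal vectors of two crystals."""
    angles = []
    ratios = []
    for u, v in ((earlier.astar, later.astar),
                 (earlier.bstar, later.bstar),
                 (earlier.cstar, later.cstar)):
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            raise ValueError("zero-length reciprocal basis vector")
        cosang = float(np.dot(u, v) / (nu * nv))
        angles.append(math.degrees(math.acos(max(-1.0, min(1.0, cosang)))))
        ratios.append(float(nv / nu))
    return OrientationChange(angles[0], angles[1], angles[2],
                             ratios[0], ratios[1], ratios[2])


@dataclass
class ClassificationResult:
    """Labels per crystal plus the matched consecutive-hit links.

    ``labels`` is keyed by (frame position, crystal position in frame).
    ``links`` holds every matched consecutive pair, including links deep in
    chains of length >= 3; ``pairs`` restricts to the FIRST->SECOND pairs
    that enter double-hit statistics.
    """

    labels: dict[tuple[int, int], HitLabel] = field(default_factory=dict)
    links: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)

    @property
    def pairs(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        return [(a, b) for a, b in self.links
                if self.labels[a] is HitLabel.FIRST]

    def count(self, label: HitLabel) -> int:
        return sum(1 for v in self.labels.values() if v is label)


def _adjacent_frame_pairs(dataset: StreamDataset, criteria: MultiHitCriteria):
    """Yield (i, j) frame positions that count as consecutive pulses."""
    frames = dataset.frames
    for i in range(len(frames) - 1):
        a, b = frames[i], frames[i + 1]
        if criteria.require_same_train and a.train_id != b.train_id:
            continue
        if criteria.require_adjacent_pulse:
            if a.train_id == b.train_id and b.pulse_id - a.pulse_id != 1:
                continue
        yield i, i + 1


def classify(dataset: StreamDataset,
             criteria: MultiHitCriteria | None = None) -> ClassificationResult:
    """Label every indexed crystal SINGLE / FIRST / SECOND / RUN_EXTRA.

    Candidate pairs come from consecutive frames on adjacent pulses of the
    same train (non-indexed frames in between do not matter: only pulse-id
    arithmetic does).  Within one frame pair, crystals are matched greedily
    by smallest summary angle, each crystal in at most one pair; ties break
    by crystal order in the file.  Matched links that share a crystal across
    successive frame pairs form chains: the first two members are labelled
    FIRST and SECOND, later members RUN_EXTRA.
    """
    criteria = criteria or MultiHitCriteria()
    result = ClassificationResult()
    for fi, frame in enumerate(dataset.frames):
        for ci in range(len(frame.crystals)):
            result.labels[(fi, ci)] = HitLabel.SINGLE

    succ: dict[tuple[int, int], tuple[int, int]] = {}
    pred: dict[tuple[int, int], tuple[int, int]] = {}
    for i, j in _adjacent_frame_pairs(dataset, criteria):
        earlier, later = dataset.frames[i], dataset.frames[j]
        candidates = []
        for p, cp in enumerate(earlier.crystals):
            for q, cq in enumerate(later.crystals):
                ch = orientation_change(cp, cq)
                if ch.passes(criteria):
                    candidates.append((ch.summary_angle, p, q))
        candidates.sort()
        used_p: set[int] = set()
        used_q: set[int] = set()
        for _, p, q in candidates:
            if p in used_p or q in used_q:
                continue
            used_p.add(p)
            used_q.add(q)
            succ[(i, p)] = (j, q)
            pred[(j, q)] = (i, p)
            result.links.append(((i, p), (j, q)))

    # walk chains from their start nodes
    for node in succ:
        if node in pred:
            continue
        chain = [node]
        while chain[-1] in succ:
            chain.append(succ[chain[-1]])
        result.labels[chain[0]] = HitLabel.FIRST
        result.labels[chain[1]] = HitLabel.SECOND
        for extra in chain[2:]:
            result.labels[extra] = HitLabel.RUN_EXTRA
    return result


@dataclass
class OrientationHistogram:
    """Relative frequency of the summary angle over adjacent-pulse pairs."""

    bin_edges: np.ndarray     # degrees, covering [0, 180]
    frequency: np.ndarray     # sums to 1 when n_pairs > 0
    n_pairs: int

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0

    def mass_below(self, angle: float) -> float:
        """Total relative frequency in bins entirely below ``angle``."""
        sel = self.bin_edges[1:] <= angle + 1e-12
        return float(self.frequency[sel].sum())


def orientation_histogram(dataset: StreamDataset, bin_width: float = 1.0,
                          criteria: MultiHitCriteria | None = None
                          ) -> OrientationHistogram:
    """Histogram of orientation change across all adjacent-pulse crystal pairs.

    All crystal cross-pairs between the two frames contribute, matched or
    not — this is the diagnostic that shows the double-hit excess at small
    angles over the uniform-rotation background.
    """
    criteria = criteria or MultiHitCriteria()
    angles = []
    for i, j in _adjacent_frame_pairs(dataset, criteria):
        for cp in dataset.frames[i].crystals:
            for cq in dataset.frames[j].crystals:
                angles.append(orientation_change(cp, cq).summary_angle)
    n_bins = int(math.ceil(180.0 / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    if not angles:
        return OrientationHistogram(edges, np.zeros(n_bins), 0)
    counts, _ = np.histogram(angles, bins=edges)
    return OrientationHistogram(edges, counts / counts.sum(), len(angles))


@dataclass(frozen=True)
class RunSummary:
    """Run statistics in the layout of an experiment summary table."""

    n_frames: int
    n_hits: int
    n_indexed: int
    n_double_hit_frames: int
    n_single_hits: int

    @property
    def hit_rate(self) -> float:
        """Percent of collected frames with a detected hit."""
        return 100.0 * self.n_hits / self.n_frames

    @property
    def index_rate(self) -> float:
        """Percent of hits that were indexed."""
        return 100.0 * self.n_indexed / self.n_hits if self.n_hits else 0.0

    @property
    def n_double_hit_pairs(self) -> int:
        return self.n_double_hit_frames // 2

    @property
    def double_hit_pct(self) -> float:
        """Percent of distinct crystals (pairs + singles) hit twice."""
        crystals = self.n_double_hit_pairs + self.n_single_hits
        return 100.0 * self.n_double_hit_pairs / crystals if crystals else 0.0


def summarize(dataset: StreamDataset, result: ClassificationResult,
              n_frames: int | None = None,
              n_hits: int | None = None) -> RunSummary:
    """Build a :class:`RunSummary` from classification output.

    ``n_frames`` (total frames collected, including blanks not present in
    the stream) and ``n_hits`` (hit-finder positives) may be supplied from
    external bookkeeping; by default every frame in the stream counts as a
    hit candidate and frames with >= 1 crystal count as indexed.
    """
    if len(dataset.frames) == 0 and n_frames is None:
        raise ValueError("empty dataset and no external frame count")
    n_indexed = sum(1 for f in dataset.frames if f.crystals)
    if n_hits is None:
        n_hits = len(dataset.frames)
    if n_frames is None:
        n_frames = len(dataset.frames)
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    n_double = result.count(HitLabel.FIRST) + result.count(HitLabel.SECOND)
    n_single = result.count(HitLabel.SINGLE)
    return RunSummary(n_frames=n_frames, n_hits=n_hits, n_indexed=n_indexed,
                      n_double_hit_frames=n_double, n_single_hits=n_single)


def split(dataset: StreamDataset, result: ClassificationResult
          ) -> tuple[StreamDataset, StreamDataset, StreamDataset]:
    """Split into (singles, first hits, second hits) datasets.

    The three outputs are disjoint; firsts and seconds have equal crystal
    counts; RUN_EXTRA crystals are dropped entirely.
    """
    outputs = {HitLabel.SINGLE: StreamDataset(), HitLabel.FIRST: StreamDataset(),
               HitLabel.SECOND: StreamDataset()}
    for ds in outputs.values():
        ds.photon_energy_kev = dataset.photon_energy_kev
        ds.pulse_spacing_ns = dataset.pulse_spacing_ns
        ds.jet_label = dataset.jet_label
    for fi, frame in enumerate(dataset.frames):
        per_label: dict[HitLabel, list] = {}
        for ci, cry in enumerate(frame.crystals):
            label = result.labels[(fi, ci)]
            if label is HitLabel.RUN_EXTRA:
                continue
            per_label.setdefault(label, []).append(cry)
        for label, crystals in per_label.items():
            out = outputs[label]
            out.frames.append(type(frame)(
                frame_index=len(out.frames), train_id=frame.train_id,
                pulse_id=frame.pulse_id, event_label=frame.event_label,
                filename=frame.filename, crystals=crystals))
    return (outputs[HitLabel.SINGLE], outputs[HitLabel.FIRST],
            outputs[HitLabel.SECOND])
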