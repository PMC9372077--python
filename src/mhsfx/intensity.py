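"""Data-quality diagnostics: SNR filtering, powder-style intensity profiles,
and half-set correlation metrics (CC1/2 and CC*).

The powder profile is the mean integrated Bragg intensity binned in 1/d,
normalised to a maximum of one — a scale-free way to compare the diffraction
strength of datasets of very different sizes (single vs first vs second
hits).  CC* estimates the correlation of a merged dataset against the true
underlying intensities from the half-set correlation CC1/2 via
``CC* = sqrt(2 CC1/2 / (1 + CC1/2))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np

from .stream_io import Reflection, StreamDataset, resolution_of

__all__ = [
    "PowderProfile",
    "MergeQuality",
    "filter_snr",
    "powder_profile",
    "wilson_b",
    "cc_star",
    "split_half_cc",
]


@dataclass
class PowderProfile:
    """Mean integrated intensity vs 1/d, normalised to max = 1."""

    bin_edges: np.ndarray      # 1/d in A^-1, contiguous
    intensity: np.ndarray      # normalised per-bin mean; NaN for empty bins

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class MergeQuality:
    cc_half: float
    cc_star: float
    n_common: int


def filter_snr(reflections: list[Reflection],
               threshold: float = 2.0) -> list[Reflection]:
    """Keep reflections with I/sigma(I) strictly above ``threshold``."""
    return [r for r in reflections if r.intensity / r.sigma > threshold]


def powder_profile(dataset: StreamDataset, bin_width: float = 0.01,
                   snr_threshold: float = 2.0) -> PowderProfile:
    """Normalised mean-intensity profile in 1/d over all crystals.

    Reflections are SNR-filtered first; each surviving reflection is placed
    in a 1/d bin using its own crystal's cell; per-bin means are divided by
    the largest bin mean.
    """
    s_vals: list[float] = []
    i_vals: list[float] = []
    for _, _, cry in dataset.iter_crystals():
        for r in filter_snr(cry.reflections, snr_threshold):
            s_vals.append(1.0 / resolution_of(r, cry.cell))
            i_vals.append(r.intensity)
    if not s_vals:
        raise ValueError("no reflections survive the SNR filter")
    s = np.asarray(s_vals)
    i = np.asarray(i_vals)
    n_bins = int(math.ceil(s.max() / bin_width)) or 1
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    idx = np.clip(np.digitize(s, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=i, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PowderProfile(edges, means / np.nanmax(means))


def wilson_b(profile: PowderProfile, s_min: float = 0.0) -> float:
    """Overall Wilson B (A^2) from the intensity falloff I ~ exp(-B s^2 / 2).

    Fits ln(I) against s^2 = (1/d)^2 over non-empty bins with s > ``s_min``
    (low-resolution bins where the Wilson approximation fails can be cut).
    """
    s = profile.bin_centers
    ok = np.isfinite(profile.intensity) & (profile.intensity > 0) & (s > s_min)
    if ok.sum() < 2:
        raise ValueError("need at least two populated bins for a Wilson fit")
    slope, _ = np.polyfit(s[ok] ** 2, np.log(profile.intensity[ok]), 1)
    return -2.0 * slope


def cc_star(cc_half: float, permissive: bool = False) -> float:
    """Estimated correlation against true intensities, from CC1/2."""
    if cc_half <= -1:
        raise ValueError("cc_half must exceed -1")
    if cc_half < 0 and not permissive:
        raise ValueError("negative cc_half; pass permissive=True to allow")
    val = 2.0 * cc_half / (1.0 + cc_half)
    return math.copysign(math.sqrt(abs(val)), cc_half)


def split_half_cc(dataset: StreamDataset, seed: int = 0,
                  spacegroup: str = "P 43 21 2",
                  snr_threshold: float | None = None) -> MergeQuality:
    """Half-set correlation of merged intensities, crystal-wise split.

    Crystals are randomly partitioned into two halves; within each half,
    reflections are mapped to the reciprocal-space asymmetric unit of the
    configured space group's Laue class and averaged per unique index; the
    Pearson correlation over unique reflections present in both halves is
    CC1/2, from which CC* follows.
    """
    crystals = [cry for _, _, cry in dataset.iter_crystals()]
    if len(crystals) < 2:
        raise ValueError("need at least two crystals to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(crystals))
    half_a = set(order[: len(crystals) // 2].tolist())

    sg = gemmi.SpaceGroup(spacegroup)
    asu = gemmi.ReciprocalAsu(sg)
    ops = sg.operations()

    def merge(idx_set_is_a: bool) -> dict[tuple[int, int, int], float]:
        sums: dict[tuple[int, int, int], list[float]] = {}
        for ci, cry in enumerate(crystals):
            if (ci in half_a) != idx_set_is_a:
                continue
            refl = cry.reflections
            if snr_threshold is not None:
                refl = filter_snr(refl, snr_threshold)
            for r in refl:
                key, _ = asu.to_asu((r.h, r.k, r.l), ops)
                sums.setdefault(tuple(key), []).append(r.intensity)
        return {k: float(np.mean(v)) for k, v in sums.items()}

    a = merge(True)
    b = merge(False)
    common = sorted(set(a) & set(b))
    if len(common) < 2:
        raise ValueError("fewer than two unique reflections common to both halves")
    ia = np.array([a[k] for k in common])
    ib = np.array([b[k] for k in common])
    if ia.std() == 0 or ib.std() == 0:
        cc = 1.0 if np.allclose(ia, ib) else 0.0
    else:
        cc = float(np.corrcoef(ia, ib)[0, 1])
    return MergeQuality(cc_half=cc, cc_star=cc_star(cc, permissive=True),
                        n_common=len(common))
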