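"""Synthetic stream files and beam images with planted ground truth.

The stream generator emulates the statistical structure the multi-hit
analysis relies on: pulse trains at a fixed intra-train spacing, crystals
arriving in the jet as a Poisson process, uniformly random crystal
orientations with a small random tumble between consecutive pulses, a 1D
Lorentzian fluence profile across the interaction region, Wilson-type
intensity falloff with resolution, and multiplicative measurement noise.

A crystal is "hit" whenever at least ``min_interaction`` of it overlaps the
beam full width; the effective hit window can be overridden (or set via
``hit_window_for_double_fraction``) to plant a chosen double-hit fraction.
Diffraction is phenomenological: every hit yields an indexed crystal with a
reflection list; hit-finding and indexing are not separately simulated,
though a configurable fraction of orphan (crystal-less) frames exercises
parser robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .beam_profile import FW_FACTOR, BeamImage
from .multihit import HitLabel
from .stream_io import (FrameRecord, IndexedCrystal, Reflection, StreamDataset,
                        UnitCell, resolution_of)
from .transit import CrystalParams, JetParams, TrainStructure

__all__ = [
    "LYSOZYME_CELL",
    "SimConfig",
    "CrystalTruth",
    "GroundTruth",
    "PRESETS",
    "hit_window_for_double_fraction",
    "simulate_stream",
    "simulate_beam_image",
]

# tetragonal hen egg-white lysozyme, P43212
LYSOZYME_CELL = UnitCell(79.30, 79.30, 37.73, 90.0, 90.0, 90.0)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the stream generator.

    Defaults mirror the slow-jet experiment: 42 m/s jet, 886 ns pulse
    spacing, mean beam widths FWHM 18.7 / FW 65.8 um, 8 um crystals, and a
    Wilson B of 19.58 A^2 for the intensity falloff.
    """

    jet: JetParams = field(default_factory=lambda: JetParams(42.0))
    train: TrainStructure = field(
        default_factory=lambda: TrainStructure(spacing_ns=886.0,
                                               pulses_per_train=202))
    beam_fwhm_um: float = 18.7
    beam_fw_um: float = 65.8
    crystal: CrystalParams = field(default_factory=CrystalParams)
    arrival_rate: float = 0.05        # expected crystals per interpulse interval
    tumble_deg: float = 1.0           # half-normal scale of interpulse rotation
    cell: UnitCell = LYSOZYME_CELL
    wilson_b: float = 19.58           # A^2
    noise_rel: float = 0.1            # lognormal sigma on intensities
    sigma_floor: float = 1.0
    base_intensity: float = 1.0e4
    n_reflections: int = 30
    fixed_hkl: bool = False           # same reflection list for every crystal
    orphan_fraction: float = 0.0      # empty frames (hit, not indexed)
    hit_window_um: float | None = None
    n_trains: int = 10
    seed: int = 0

    @property
    def interpulse_um(self) -> float:
        return self.jet.speed * self.train.effective_spacing_ns / 1000.0

    @property
    def effective_hit_window_um(self) -> float:
        """Full width of centre positions that count as a hit."""
        if self.hit_window_um is not None:
            return self.hit_window_um
        return (self.beam_fw_um + self.crystal.edge
                - 2.0 * self.crystal.min_interaction)


def hit_window_for_double_fraction(config: SimConfig, fraction: float) -> SimConfig:
    """Return a config whose geometry plants a given double-hit fraction.

    For a hit window of width w and interpulse distance d with d < w < 2d,
    a crystal with uniform arrival phase is hit twice with probability
    w/d - 1 and once otherwise; choosing w = d (1 + fraction) plants the
    requested expected double fraction.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    return replace(config, hit_window_um=config.interpulse_um * (1.0 + fraction))


@dataclass
class CrystalTruth:
    """Planted trajectory and labels for one simulated crystal."""

    crystal_id: int
    train_id: int
    pulses: list[int]            # pulse ids at which the crystal was hit
    positions_um: list[float]    # beam-relative centre positions at those pulses
    labels: list[HitLabel]
    rotations: list[np.ndarray]  # 3x3 orientation matrix per hit


@dataclass
class GroundTruth:
    crystals: list[CrystalTruth] = field(default_factory=list)
    # (frame position in dataset, crystal position in frame) -> planted label
    labels_by_location: dict[tuple[int, int], HitLabel] = field(default_factory=dict)

    def count(self, label: HitLabel) -> int:
        return sum(1 for v in self.labels_by_location.values() if v is label)

    @property
    def double_fraction(self) -> float:
        """Planted fraction of distinct crystals that were hit >= twice."""
        n_multi = sum(1 for c in self.crystals if len(c.pulses) >= 2)
        n_single = sum(1 for c in self.crystals if len(c.pulses) == 1)
        total = n_multi + n_single
        return n_multi / total if total else 0.0


def _canonical_reciprocal_basis(cell: UnitCell) -> np.ndarray:
    """Rows a*, b*, c* in nm^-1 for the unrotated cell."""
    g = cell.to_gemmi()
    frac = np.array(g.frac.mat.tolist())   # rows are a*, b*, c* in A^-1
    return frac * 10.0                     # A^-1 -> nm^-1


def _run_labels(n_hits: int) -> list[HitLabel]:
    if n_hits == 1:
        return [HitLabel.SINGLE]
    return ([HitLabel.FIRST, HitLabel.SECOND]
            + [HitLabel.RUN_EXTRA] * (n_hits - 2))


def simulate_stream(config: SimConfig) -> tuple[StreamDataset, GroundTruth]:
    """Generate a stream dataset and its planted ground truth.

    Within each train, crystal centres are seeded as a 1D Poisson process
    along the jet axis over the span that can reach the hit window during
    the train; positions advance by the interpulse distance every pulse.
    Each crystal carries a uniform random orientation; consecutive hits add
    a small random rotation (half-normal angle of scale ``tumble_deg`` about
    a random axis).  Reflection intensities follow the local 1D Lorentzian
    fluence times a Wilson falloff times lognormal noise.
    """
    rng = np.random.default_rng(config.seed)
    d = config.interpulse_um
    w = config.effective_hit_window_um
    half_w = w / 2.0
    n_pulses = config.train.pulses_per_train
    gamma = config.beam_fw_um / FW_FACTOR
    b0 = _canonical_reciprocal_basis(config.cell)

    ds = StreamDataset(photon_energy_kev=9.232,
                       pulse_spacing_ns=config.train.effective_spacing_ns,
                       jet_label=f"{config.jet.speed:g} m/s")
    truth = GroundTruth()
    truth_by_id: dict[int, CrystalTruth] = {}
    fixed_hkls = _fixed_hkl_list(config) if config.fixed_hkl else None
    crystal_id = 0
    for train_id in range(config.n_trains):
        span = w + (n_pulses - 1) * d
        n_crystals = rng.poisson(config.arrival_rate * span / d)
        starts = rng.uniform(-half_w - (n_pulses - 1) * d, half_w, n_crystals)
        starts.sort()
        per_pulse: dict[int, list[tuple[int, float, np.ndarray]]] = {}
        for x0 in starts:
            k_lo = int(np.ceil((-half_w - x0) / d))
            k_hi = int(np.floor((half_w - x0) / d))
            ks = [k for k in range(max(k_lo, 0), min(k_hi, n_pulses - 1) + 1)]
            if not ks:
                continue
            rot = Rotation.random(rng=rng).as_matrix()
            ct = CrystalTruth(crystal_id=crystal_id, train_id=train_id,
                              pulses=list(ks), positions_um=[],
                              labels=_run_labels(len(ks)), rotations=[])
            for hit_no, k in enumerate(ks):
                if hit_no > 0 and config.tumble_deg >= 180.0:
                    # a tumble scale at or beyond a half turn means the
                    # orientation decorrelates completely between pulses
                    rot = Rotation.random(rng=rng).as_matrix()
                elif hit_no > 0 and config.tumble_deg > 0:
                    angle = abs(rng.normal(0.0, np.deg2rad(config.tumble_deg)))
                    axis = rng.normal(size=3)
                    axis /= np.linalg.norm(axis)
                    rot = Rotation.from_rotvec(angle * axis).as_matrix() @ rot
                x = x0 + k * d
                ct.positions_um.append(x)
                ct.rotations.append(rot.copy())
                per_pulse.setdefault(k, []).append((crystal_id, x, rot.copy()))
            truth.crystals.append(ct)
            truth_by_id[crystal_id] = ct
            crystal_id += 1

        for k in sorted(set(per_pulse) |
                        ({p for p in range(n_pulses)
                          if rng.random() < config.orphan_fraction}
                         if config.orphan_fraction > 0 else set())):
            entries = per_pulse.get(k, [])
            frame = FrameRecord(frame_index=len(ds.frames), train_id=train_id,
                                pulse_id=k, event_label=f"//{train_id}-{k}")
            for ci, (cid, x, rot) in enumerate(entries):
                basis = b0 @ rot.T   # rotate each reciprocal row vector
                fluence_factor = gamma**2 / (x**2 + gamma**2)
                frame.crystals.append(_make_crystal(
                    basis, config, fluence_factor, rng, fixed_hkls))
                ct = truth_by_id[cid]
                hit_no = ct.pulses.index(k)
                truth.labels_by_location[(frame.frame_index, ci)] = ct.labels[hit_no]
            ds.frames.append(frame)
    return ds, truth


def _fixed_hkl_list(config: SimConfig) -> list[tuple[int, int, int]]:
    """Deterministic reflection list: lowest-resolution indices first."""
    out = []
    for h in range(0, 13):
        for k in range(0, 13):
            for l in range(0, 7):
                if (h, k, l) == (0, 0, 0):
                    continue
                d = resolution_of((h, k, l), config.cell)
                if d >= 1.7:
                    out.append((d, (h, k, l)))
    out.sort(reverse=True)
    return [hkl for _, hkl in out[: config.n_reflections]]


def _make_crystal(basis: np.ndarray, config: SimConfig,
                  fluence_factor: float, rng: np.random.Generator,
                  fixed_hkls: list[tuple[int, int, int]] | None = None
                  ) -> IndexedCrystal:
    reflections: list[Reflection] = []
    if config.n_reflections > 0:
        if fixed_hkls is not None:
            hkls: list[tuple[int, int, int]] = fixed_hkls
        else:
            seen: set[tuple[int, int, int]] = set()
            hs = rng.integers(-20, 21, size=4 * config.n_reflections)
            ks = rng.integers(-20, 21, size=4 * config.n_reflections)
            ls = rng.integers(-9, 10, size=4 * config.n_reflections)
            hkls = []
            for h, k, l in zip(hs, ks, ls):
                hkl = (int(h), int(k), int(l))
                if hkl == (0, 0, 0) or hkl in seen:
                    continue
                seen.add(hkl)
                if resolution_of(hkl, config.cell) < 1.7:
                    continue   # outside the simulated resolution limit
                hkls.append(hkl)
                if len(hkls) >= config.n_reflections:
                    break
        for hkl in hkls:
            s = 1.0 / resolution_of(hkl, config.cell)
            mean_i = (config.base_intensity * fluence_factor
                      * np.exp(-config.wilson_b * s**2 / 2.0))
            noise = (np.exp(rng.normal(0.0, config.noise_rel))
                     if config.noise_rel > 0 else 1.0)
            intensity = mean_i * noise
            sigma = config.sigma_floor + np.sqrt(max(intensity, 0.0))
            reflections.append(Reflection(*hkl, float(intensity), float(sigma)))
    return IndexedCrystal(astar=basis[0], bstar=basis[1], cstar=basis[2],
                          cell=config.cell, reflections=reflections,
                          resolution_limit=1.7)


PRESETS: dict[str, SimConfig] = {
    "42ms": SimConfig(jet=JetParams(42.0)),
    "78ms": SimConfig(jet=JetParams(78.0), arrival_rate=0.02),
    "102ms": SimConfig(jet=JetParams(102.0), arrival_rate=0.01),
}


def simulate_beam_image(gamma_um: float = 9.35, pixel_size_um: float = 0.65,
                        shape: tuple[int, int] = (121, 121),
                        psf_fwhm_um: float = 0.0, noise_level: float = 0.0,
                        peak_counts: float = 4000.0,
                        seed: int = 0) -> BeamImage:
    """Synthetic scintillator footprint: separable 2D Lorentzian, optional
    Gaussian PSF blur and Poisson-like counting noise.

    ``noise_level`` scales the Poisson noise: 0 gives a noiseless image,
    1 gives shot noise at ``peak_counts`` peak intensity.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel_size_um
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_size_um
    ly = gamma_um**2 / (y**2 + gamma_um**2)
    lx = gamma_um**2 / (x**2 + gamma_um**2)
    img = peak_counts * np.outer(ly, lx)
    if psf_fwhm_um > 0:
        sigma_px = psf_fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0))) / pixel_size_um
        img = ndimage.gaussian_filter(img, sigma_px)
    if noise_level > 0:
        img = rng.poisson(img / noise_level**2).astype(float) * noise_level**2
    return BeamImage(data=img, pixel_size_um=pixel_size_um)
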