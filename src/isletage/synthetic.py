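"""Synthetic data generators with known ground truth.

Every input the analysis stages consume can be generated here: labeled-cell
cohorts under diet-dependent turnover, multi-channel MIMS count rasters with
Poisson ion statistics, multi-run TF->target edge lists around an embedded
true network, cells x regulons activity matrices, per-ion intensity images
over labeled tissue regions, and glucose/insulin tolerance curves with known
exponential decay rates.

All generators are pure functions of (parameters, seed): the same inputs
produce byte-identical outputs. Ground truth (division counts, ON labels,
true edges, effect sizes, decay rates) is always returned alongside the data
so every downstream stage has a recovery target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .birthdating import label_after_divisions
from .phenotyping import ToleranceCurve

# Natural 15N abundance (atom fraction). A physical constant, exposed so the
# labeling protocol can override it.
F_NAT = 0.0037

#: Diet groups used throughout: ad libitum, caloric restriction, high-fat diet.
DIET_GROUPS = ("AL", "CR", "HFD")


@dataclass(frozen=True)
class LabelingProtocol:
    """Stable-isotope labeling design: a 15N-saturating diet followed by a
    14N chase during which cell division halves nuclear label excess.

    Parameters
    ----------
    diet_enrichment:
        15N atom fraction of the labeling diet (> 0.98 for commercial feed).
    natural_abundance:
        Baseline 15N atom fraction ``f_nat``.
    initial_excess:
        ``e0``, the saturation atom fraction minus ``f_nat``.  Defaults to
        ``diet_enrichment - natural_abundance``, a stand-in for the measured
        saturation level which is instrument-dependent.
    chase_months:
        Duration of the 14N chase in months.
    """

    diet_enrichment: float = 0.98
    natural_abundance: float = F_NAT
    initial_excess: float | None = None
    chase_months: float = 12.0

    def __post_init__(self):
        e0 = self.e0
        if not (0.0 < self.natural_abundance < self.natural_abundance + e0 <= 1.0):
            raise ValueError(
                "require 0 < f_nat < f_nat + e0 <= 1, got "
                f"f_nat={self.natural_abundance}, e0={e0}"
            )
        if self.chase_months < 0:
            raise ValueError("chase_months must be >= 0")

    @property
    def e0(self) -> float:
        if self.initial_excess is not None:
            return self.initial_excess
        return self.diet_enrichment - self.natural_abundance


@dataclass(frozen=True)
class TurnoverParams:
    """Two-component turnover model for one diet group.

    A cell is quiescent (never divides during the chase) with probability
    ``p_quiescent``; otherwise its division count is Poisson with mean
    ``division_rate * chase_months``.  This formalizes the reserve-pool view
    of beta-cell heterogeneity: a long-lived fraction plus a cycling fraction.
    """

    group: str
    p_quiescent: float
    division_rate: float  # expected divisions per cycling cell per month

    def __post_init__(self):
        if not 0.0 <= self.p_quiescent <= 1.0:
            raise ValueError(f"p_quiescent must be in [0, 1], got {self.p_quiescent}")
        if self.division_rate < 0:
            raise ValueError(f"division_rate must be >= 0, got {self.division_rate}")


#: Default turnover parameters per diet group.  Chosen to reflect the
#: reported 12-month outcomes (CR beta cells ~80% long-lived, HFD ~30%,
#: AL intermediate); see docs/methods.md.
DEFAULT_TURNOVER = {
    "CR": TurnoverParams("CR", p_quiescent=0.80, division_rate=0.10),
    "AL": TurnoverParams("AL", p_quiescent=0.55, division_rate=0.20),
    "HFD": TurnoverParams("HFD", p_quiescent=0.30, division_rate=0.40),
}


@dataclass(frozen=True)
class SimCell:
    """A simulated cell with latent division count and resulting label excess."""

    cell_id: str
    cell_type: str  # beta | alpha | delta | acinar | neuron
    group: str
    true_divisions: int
    true_excess: float


def simulate_cohort(
    protocol: LabelingProtocol,
    params: TurnoverParams,
    n_cells: int,
    seed: int,
    cell_type: str = "beta",
) -> list[SimCell]:
    """Draw a cohort of cells with latent division counts under one diet.

    Each cell is quiescent (k = 0) with probability ``p_quiescent``;
    otherwise k ~ Poisson(division_rate * chase_months).  Nuclear label
    excess is ``e0 * 0.5**k``.  Neurons are post-mitotic: k = 0 always.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    lam = params.division_rate * protocol.chase_months
    quiescent = rng.random(n_cells) < params.p_quiescent
    k = rng.poisson(lam, size=n_cells)
    k[quiescent] = 0
    if cell_type == "neuron":
        k[:] = 0
    cells = []
    for i, ki in enumerate(k):
        cells.append(
            SimCell(
                cell_id=f"{params.group}_{cell_type}_{i:05d}",
                cell_type=cell_type,
                group=params.group,
                true_divisions=int(ki),
                true_excess=label_after_divisions(protocol.e0, int(ki)),
            )
        )
    return cells


def cohort_to_frame(cells: list[SimCell]) -> pd.DataFrame:
    """Cohort as a DataFrame (cell_id, cell_type, group, true_divisions, true_excess)."""
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "cell_type": [c.cell_type for c in cells],
            "group": [c.group for c in cells],
            "true_divisions": [c.true_divisions for c in cells],
            "true_excess": [c.true_excess for c in cells],
        }
    )


# ---------------------------------------------------------------------------
# MIMS raster synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MIMSSynthConfig:
    """Parameters for synthetic MIMS count rasters.

    ``dose_per_pixel`` is the expected total ion count (15N + 14N) per pixel
    per frame inside a nucleus; channel means split it by atom fraction:
    15N ~ Poisson(D * f * h) and 14N ~ Poisson(D * (1 - f) * h), with h the
    local hotspot factor.  Heterochromatin hotspots model locally denser DNA:
    they scale the dose (more N atoms sputtered) but not the atom fraction.
    """

    shape: tuple[int, int] = (512, 512)
    n_frames: int = 3
    dose_per_pixel: float = 200.0
    background_dose: float = 2.0
    nucleus_radius_range: tuple[float, float] = (8.0, 14.0)
    hotspot_factor: float = 2.0
    hotspot_fraction: float = 0.15
    f_nat: float = F_NAT
    n_fiducials: int = 4
    fiducial_dose: float = 500.0


def _place_nuclei(rng, shape, radii):
    """Rejection-sample non-overlapping disk centers; error if they cannot fit."""
    h, w = shape
    centers = []
    for r in radii:
        placed = False
        for _ in range(2000):
            cy = rng.uniform(r + 1, h - r - 1)
            cx = rng.uniform(r + 1, w - r - 1)
            if all(
                (cy - oy) ** 2 + (cx - ox) ** 2 > (r + orad + 2) ** 2
                for oy, ox, orad in centers
            ):
                centers.append((cy, cx, r))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"raster {shape} too small to place {len(radii)} non-overlapping nuclei"
            )
    return centers


def synthesize_mims_frames(
    cells: list[SimCell],
    config: MIMSSynthConfig,
    seed: int,
):
    """Render cells as nuclei in a stack of MIMS count frames.

    Returns ``(frames, label_mask, truth)`` where ``frames`` is a list of
    :class:`~isletage.mims.MIMSFrame` (one per accumulation frame),
    ``label_mask`` is an integer raster with nucleus i labeled ``i + 1``
    (0 = background), and ``truth`` maps label id -> SimCell.

    Expected counts are conserved before Poisson sampling: the expectation
    raster for each channel is dose x atom-fraction x hotspot, exactly.
    """
    from .mims import MIMSFrame

    rng = np.random.default_rng(seed)
    h, w = config.shape
    radii = rng.uniform(*config.nucleus_radius_range, size=len(cells))
    centers = _place_nuclei(rng, config.shape, radii)

    label_mask = np.zeros((h, w), dtype=np.uint16)
    f_map = np.full((h, w), config.f_nat)
    dose_map = np.full((h, w), config.background_dose)
    yy, xx = np.mgrid[0:h, 0:w]
    truth: dict[int, SimCell] = {}
    for i, (cell, (cy, cx, r)) in enumerate(zip(cells, centers)):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        label_mask[disk] = i + 1
        f_map[disk] = config.f_nat + cell.true_excess
        dose_map[disk] = config.dose_per_pixel
        # heterochromatin hotspots: denser DNA, same atom fraction
        if config.hotspot_fraction > 0 and config.hotspot_factor != 1.0:
            hot = disk & (rng.random((h, w)) < config.hotspot_fraction)
            dose_map[hot] *= config.hotspot_factor
        truth[i + 1] = cell

    mean15 = dose_map * f_map
    mean14 = dose_map * (1.0 - f_map)
    mean32 = np.full((h, w), 0.5)
    for _ in range(config.n_fiducials):
        fy = int(rng.uniform(5, h - 5))
        fx = int(rng.uniform(5, w - 5))
        mean32[fy - 2 : fy + 3, fx - 2 : fx + 3] = config.fiducial_dose

    frames = []
    for _ in range(config.n_frames):
        frames.append(
            MIMSFrame(
                channels={
                    "15N": rng.poisson(mean15).astype(np.int64),
                    "14N": rng.poisson(mean14).astype(np.int64),
                    "32S": rng.poisson(mean32).astype(np.int64),
                },
                pixel_size_nm=70.0,
                n_frames_accumulated=1,
            )
        )
    return frames, label_mask, truth


def expected_channel_means(cells, config: MIMSSynthConfig, seed: int):
    """Pre-sampling expectation rasters (15N, 14N) for the same seed.

    Used to verify expectation conservation: regenerates the geometry with the
    same RNG stream as :func:`synthesize_mims_frames` and returns the exact
    dose x atom-fraction products.
    """
    rng = np.random.default_rng(seed)
    h, w = config.shape
    radii = rng.uniform(*config.nucleus_radius_range, size=len(cells))
    centers = _place_nuclei(rng, config.shape, radii)
    f_map = np.full((h, w), config.f_nat)
    dose_map = np.full((h, w), config.background_dose)
    yy, xx = np.mgrid[0:h, 0:w]
    for cell, (cy, cx, r) in zip(cells, centers):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        f_map[disk] = config.f_nat + cell.true_excess
        dose_map[disk] = config.dose_per_pixel
        if config.hotspot_fraction > 0 and config.hotspot_factor != 1.0:
            hot = disk & (rng.random((h, w)) < config.hotspot_fraction)
            dose_map[hot] *= config.hotspot_factor
    return dose_map * f_map, dose_map * (1.0 - f_map)


def simulate_nucleus_counts(
    cells: list[SimCell],
    total_dose: float,
    seed: int,
    f_nat: float = F_NAT,
):
    """Poisson ion-count measurements for a cohort, bypassing raster geometry.

    For each cell with atom fraction f = f_nat + e, draws
    sum15 ~ Poisson(total_dose * f) and sum14 ~ Poisson(total_dose * (1-f))
    — the counting statistics a whole-nucleus ROI would accumulate at the
    given total dose — and returns :class:`~isletage.mims.NucleusMeasurement`
    objects.  Much faster than rendering full rasters; used for large
    replicate experiments.
    """
    from .mims import NucleusMeasurement

    rng = np.random.default_rng(seed)
    out = []
    for i, cell in enumerate(cells):
        f = f_nat + cell.true_excess
        s15 = float(rng.poisson(total_dose * f))
        s14 = float(rng.poisson(total_dose * (1.0 - f)))
        if s14 == 0:
            s14 = 1.0  # degenerate draw at tiny dose; keep measurable
        fhat = s15 / (s15 + s14)
        out.append(
            NucleusMeasurement(
                label_id=i + 1,
                sum15=s15,
                sum14=s14,
                ratio=s15 / s14,
                atom_fraction=fhat,
                excess=fhat - f_nat,
                area_px=0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# GRN run sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GRNTruth:
    """An embedded true network: (tf, target) -> importance weight."""

    true_edges: dict[tuple[str, str], float]
    n_tfs: int
    n_targets: int

    def __post_init__(self):
        for (tf, tgt), imp in self.true_edges.items():
            if tf == tgt:
                raise ValueError(f"self-edge {tf}->{tgt} not allowed")
            if imp <= 0:
                raise ValueError(f"importance must be > 0, got {imp} for {tf}->{tgt}")


def random_grn_truth(n_tfs: int, n_targets: int, n_edges: int, seed: int) -> GRNTruth:
    """A random bipartite TF->target truth with lognormal importances."""
    rng = np.random.default_rng(seed)
    tfs = [f"TF{i:03d}" for i in range(n_tfs)]
    targets = [f"G{i:04d}" for i in range(n_targets)]
    all_pairs = [(tf, g) for tf in tfs for g in targets]
    if n_edges > len(all_pairs):
        raise ValueError("n_edges exceeds number of possible TF->target pairs")
    idx = rng.choice(len(all_pairs), size=n_edges, replace=False)
    importances = rng.lognormal(mean=1.0, sigma=0.5, size=n_edges)
    edges = {all_pairs[i]: float(w) for i, w in zip(idx, importances)}
    return GRNTruth(true_edges=edges, n_tfs=n_tfs, n_targets=n_targets)


def synthesize_grn_runs(
    truth: GRNTruth,
    n_runs: int,
    p_true: float,
    p_false: float,
    seed: int,
    noise_sigma: float = 0.1,
):
    """Simulate stochastic network-inference runs around a true network.

    Each run contains each true edge independently with probability
    ``p_true`` (importance = true weight x lognormal multiplicative noise)
    and each non-edge with probability ``p_false`` (small spurious
    importance).  Returns a :class:`~isletage.grn.RunSet`.
    """
    from .grn import RunSet

    if not (0.0 <= p_false <= p_true <= 1.0):
        raise ValueError(f"require 0 <= p_false <= p_true <= 1, got {p_false}, {p_true}")
    rng = np.random.default_rng(seed)
    tfs = [f"TF{i:03d}" for i in range(truth.n_tfs)]
    targets = [f"G{i:04d}" for i in range(truth.n_targets)]
    non_edges = [
        (tf, g) for tf in tfs for g in targets if (tf, g) not in truth.true_edges
    ]
    runs = []
    for _ in range(n_runs):
        edges = []
        for (tf, tgt), w in truth.true_edges.items():
            if rng.random() < p_true:
                noisy = w * rng.lognormal(0.0, noise_sigma)
                edges.append((tf, tgt, float(noisy)))
        if p_false > 0 and non_edges:
            keep = rng.random(len(non_edges)) < p_false
            for (tf, tgt), k in zip(non_edges, keep):
                if k:
                    edges.append((tf, tgt, float(rng.lognormal(-1.0, noise_sigma))))
        runs.append(edges)
    return RunSet(runs=runs)


# ---------------------------------------------------------------------------
# Regulon activity matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegulonSpec:
    """Bimodal activity spec for one regulon column.

    ON cells draw from Normal(on_mean, on_sd), OFF cells from
    Normal(off_mean, off_sd); draws are clipped to [0, 1] like rank-based
    activity scores.
    """

    name: str
    on_fraction: float
    on_mean: float = 0.8
    on_sd: float = 0.05
    off_mean: float = 0.1
    off_sd: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.on_fraction <= 1.0:
            raise ValueError("on_fraction must be in [0, 1]")
        for m in (self.on_mean, self.off_mean):
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"mode mean {m} outside [0, 1]")


def synthesize_activity_matrix(
    n_cells: int,
    regulon_specs: list[RegulonSpec],
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cells x regulons activity matrix with ground-truth ON labels.

    Returns ``(activity, on_labels)`` as DataFrames indexed by cell id with
    one column per regulon; activities in [0, 1], labels boolean.
    """
    rng = np.random.default_rng(seed)
    index = [f"cell{i:05d}" for i in range(n_cells)]
    act = {}
    labels = {}
    for spec in regulon_specs:
        on = rng.random(n_cells) < spec.on_fraction
        vals = np.where(
            on,
            rng.normal(spec.on_mean, spec.on_sd, n_cells),
            rng.normal(spec.off_mean, spec.off_sd, n_cells),
        )
        act[spec.name] = np.clip(vals, 0.0, 1.0)
        labels[spec.name] = on
    return (
        pd.DataFrame(act, index=index),
        pd.DataFrame(labels, index=index),
    )


# ---------------------------------------------------------------------------
# Ion images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IonSpec:
    """Lognormal intensity model for one ion over two labeled regions.

    ``effect_size`` is the shift (in log-intensity units) of region B above
    region A; zero effect makes the regions exchangeable.
    """

    mz: float
    effect_size: float
    base_log_mean: float = 2.0
    log_sd: float = 0.5

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("mz must be > 0")


def synthesize_ion_images(
    region_a_mask: np.ndarray,
    region_b_mask: np.ndarray,
    ion_specs: list[IonSpec],
    seed: int,
):
    """Per-ion intensity images over two disjoint labeled regions.

    Returns a list of :class:`~isletage.maldi.IonImage`, one per spec, with
    pixel intensities lognormal per region and zero outside both regions.
    """
    from .maldi import IonImage

    if region_a_mask.shape != region_b_mask.shape:
        raise ValueError("region masks must share shape")
    if np.any(region_a_mask & region_b_mask):
        raise ValueError("region masks must be disjoint")
    if not region_a_mask.any() or not region_b_mask.any():
        raise ValueError("both regions must be non-empty")
    rng = np.random.default_rng(seed)
    images = []
    for spec in ion_specs:
        img = np.zeros(region_a_mask.shape)
        na = int(region_a_mask.sum())
        nb = int(region_b_mask.sum())
        img[region_a_mask] = rng.lognormal(spec.base_log_mean, spec.log_sd, na)
        img[region_b_mask] = rng.lognormal(
            spec.base_log_mean + spec.effect_size, spec.log_sd, nb
        )
        images.append(IonImage(mz=spec.mz, intensities=img))
    return images


# ---------------------------------------------------------------------------
# Tolerance curves
# ---------------------------------------------------------------------------

#: Timepoints (minutes) used by the meal tolerance test: one pre-bolus sample
#: at -10 min, then post-bolus samples out to 120 min.
MTT_TIMEPOINTS = (-10.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0)

#: Insulin-tolerance-test sampling grid (minutes).
ITT_TIMEPOINTS = (0.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 60.0)


def synthesize_tolerance_curves(
    decay_rate: float,
    baseline: float,
    timepoints,
    noise_sd: float,
    seed: int,
    baseline_index: int | None = None,
) -> tuple[ToleranceCurve, float]:
    """Exponential-decay glucose curve with multiplicative lognormal noise.

    glucose(t) = baseline * exp(-decay_rate * t) * exp(noise), with
    noise ~ N(0, noise_sd^2) per timepoint.  Returns the curve and the
    ground-truth decay rate (per minute).
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    t = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    rng = np.random.default_rng(seed)
    glucose = baseline * np.exp(-decay_rate * t)
    if noise_sd > 0:
        glucose = glucose * np.exp(rng.normal(0.0, noise_sd, t.size))
    curve = ToleranceCurve(
        timepoints=t,
        glucose=glucose,
        baseline_index=0 if baseline_index is None else baseline_index,
    )
    return curve, decay_rate
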