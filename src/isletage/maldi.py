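"""Imaging-mass-spectrometry enrichment screen and accurate-mass matching.

Each detected ion gives an intensity image over the tissue section.  For two
labeled pixel classes (islet vs acinar, or AL-islet vs CR-islet) the ROC AUC
is the probability that a random class-B pixel out-ranks a random class-A
pixel (ties counted half).  Ions whose AUC deviates from 0.5 by at least a
threshold (default 0.1, inclusive, two-sided) are retained as enriched in
one class or the other.  Retained ions are tentatively identified by
accurate mass against a reference list within a hard Da tolerance
(default +/-0.00565 Da); the ppm deviation is reported diagnostically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu


@dataclass
class IonImage:
    """One ion's intensity raster at observed m/z (Da)."""

    mz: float
    intensities: np.ndarray

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("mz must be > 0")
        if (np.asarray(self.intensities) < 0).any():
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class ROCResult:
    mz: float
    auc: float
    direction: str  # "A", "B", or "none"
    retained: bool


@dataclass(frozen=True)
class MetaboliteRef:
    name: str
    mz: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("mz must be > 0")


@dataclass(frozen=True)
class MatchResult:
    observed_mz: float
    name: str
    delta_da: float
    delta_ppm: float
    matched: bool


def ion_auc(ion: IonImage, class_a_mask: np.ndarray, class_b_mask: np.ndarray) -> float:
    """ROC AUC of class-B pixel intensities against class-A.

    AUC = P(B > A) + 0.5 P(B = A), computed from the rank-sum identity
    AUC = U / (n_a * n_b) with U the Mann-Whitney statistic of B vs A.
    """
    a = np.asarray(ion.intensities)[np.asarray(class_a_mask, dtype=bool)]
    b = np.asarray(ion.intensities)[np.asarray(class_b_mask, dtype=bool)]
    return auc_from_samples(a, b)


def auc_from_samples(a: np.ndarray, b: np.ndarray) -> float:
    """Rank-sum AUC from raw intensity samples of the two classes."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both classes must be non-empty")
    u = mannwhitneyu(b, a, alternative="two-sided").statistic
    return float(u) / (a.size * b.size)


def enrichment_filter(
    aucs: list[tuple[float, float]], deviation: float = 0.1, two_sided: bool = True
) -> list[ROCResult]:
    """Retain ions whose AUC deviates from 0.5 by >= ``deviation`` (inclusive).

    ``aucs`` is a list of (mz, auc).  AUC >= 0.5 + deviation marks
    enrichment in class B; AUC <= 0.5 - deviation marks enrichment in
    class A (only with ``two_sided``).  Boundaries are inclusive.
    """
    results = []
    for mz, auc in aucs:
        if not 0.0 <= auc <= 1.0:
            raise ValueError(f"invalid AUC {auc}")
        if auc >= 0.5 + deviation:
            results.append(ROCResult(mz=mz, auc=auc, direction="B", retained=True))
        elif two_sided and auc <= 0.5 - deviation:
            results.append(ROCResult(mz=mz, auc=auc, direction="A", retained=True))
        else:
            results.append(ROCResult(mz=mz, auc=auc, direction="none", retained=False))
    return results


def match_metabolite(
    observed_mz: float, refs: list[MetaboliteRef], da_tol: float = 0.00565
) -> list[MatchResult]:
    """Accurate-mass matches within ``da_tol`` Da, sorted by |delta|.

    The Da tolerance is the hard gate (instrument mass resolution); ppm
    deviation relative to the theoretical mass is reported for each match
    as a diagnostic.  Returns an empty list when nothing matches.
    """
    if observed_mz <= 0:
        raise ValueError("observed_mz must be > 0")
    matches = []
    for ref in refs:
        delta = observed_mz - ref.mz
        # inclusive boundary; 1e-12 Da guard absorbs float representation
        # error in differences of ~500 Da masses
        if abs(delta) <= da_tol + 1e-12:
            matches.append(
                MatchResult(
                    observed_mz=observed_mz,
                    name=ref.name,
                    delta_da=delta,
                    delta_ppm=abs(delta) / ref.mz * 1e6,
                    matched=True,
                )
            )
    return sorted(matches, key=lambda m: abs(m.delta_da))


def screen_to_frame(results: list[ROCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mz": [r.mz for r in results],
            "auc": [r.auc for r in results],
            "direction": [r.direction for r in results],
            "retained": [r.retained for r in results],
        }
    )
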