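"""Synthetic stand-in for the access-controlled clinical cohort.

Generates per-patient seated MAP and measured GFR at baseline and after
3 years of CCB therapy from the published marginal moments: each (pre,
post) pair is drawn from a bivariate normal whose correlation is derived
from the published change-score SD via
``Var(post - pre) = Var(pre) + Var(post) - 2 cov``; baseline GFR is
truncated to the trial eligibility window by rejection.  Real patient-level
data, where a user holds access, can be loaded through the same CSV schema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import default_config

__all__ = ["ClinicalCohort", "generate_cohort", "cohort_moments", "derive_correlation"]

DIMENSIONS = ("map_baseline", "gfr_baseline", "map_3yr", "gfr_3yr")


@dataclass
class ClinicalCohort:
    """Per-patient MAP/GFR at baseline and 3 years."""

    patient_id: np.ndarray
    map_baseline: np.ndarray
    gfr_baseline: np.ndarray
    map_3yr: np.ndarray
    gfr_3yr: np.ndarray
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        n = len(self.patient_id)
        for dim in DIMENSIONS:
            arr = np.asarray(getattr(self, dim), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{dim}: expected shape ({n},)")
            if not np.all(arr > 0):
                raise ValueError(f"{dim}: all values must be positive")
            setattr(self, dim, arr)

    @property
    def n(self) -> int:
        return len(self.patient_id)

    def matrix(self) -> np.ndarray:
        """(n, 4) array in the canonical dimension order."""
        return np.column_stack([getattr(self, d) for d in DIMENSIONS])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": self.patient_id, **{d: getattr(self, d) for d in DIMENSIONS}}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "user-supplied") -> "ClinicalCohort":
        df = pd.read_csv(path)
        return cls(
            patient_id=df["patient_id"].to_numpy(),
            **{d: df[d].to_numpy(dtype=float) for d in DIMENSIONS},
            provenance=provenance,
        )


def derive_correlation(sd_pre: float, sd_post: float, sd_change: float) -> float:
    """Pre/post correlation implied by the change-score SD."""
    rho = (sd_pre**2 + sd_post**2 - sd_change**2) / (2.0 * sd_pre * sd_post)
    if not (-1.0 < rho < 1.0):
        raise ValueError(
            f"published moments imply infeasible correlation {rho:.3f}"
        )
    return rho


def generate_cohort(
    n: int, seed: int, moments: dict | None = None
) -> ClinicalCohort:
    """Draw a synthetic cohort of ``n`` patients from the published moments.

    Deterministic under ``seed``.  MAP and GFR blocks are independent of
    each other (no cross-moment is published); the (pre, post) pair within
    each block carries the derived correlation.
    """
    if n < 2:
        raise ValueError("cohort size must be >= 2")
    mom = moments if moments is not None else default_config()["cohort_moments"]
    rng = np.random.default_rng(seed)

    rho_map = derive_correlation(
        mom["map_baseline_sd"], mom["map_3yr_sd"], mom["map_change_sd"]
    )
    rho_gfr = derive_correlation(
        mom["gfr_baseline_sd"], mom["gfr_3yr_sd"], mom["gfr_change_sd"]
    )

    def draw_pair(mean0, sd0, mean1, sd1, rho, size):
        cov = rho * sd0 * sd1
        return rng.multivariate_normal(
            [mean0, mean1], [[sd0**2, cov], [cov, sd1**2]], size=size
        )

    map_pair = draw_pair(
        mom["map_baseline_mean"], mom["map_baseline_sd"],
        mom["map_3yr_mean"], mom["map_3yr_sd"], rho_map, n,
    )

    lo, hi = mom["gfr_baseline_window"]
    gfr_rows = []
    while sum(len(g) for g in gfr_rows) < n:
        batch = draw_pair(
            mom["gfr_baseline_mean"], mom["gfr_baseline_sd"],
            mom["gfr_3yr_mean"], mom["gfr_3yr_sd"], rho_gfr, 4 * n,
        )
        keep = (batch[:, 0] >= lo) & (batch[:, 0] <= hi) & (batch[:, 1] > 0)
        gfr_rows.append(batch[keep])
    gfr_pair = np.concatenate(gfr_rows)[:n]

    return ClinicalCohort(
        patient_id=np.arange(n),
        map_baseline=np.maximum(map_pair[:, 0], 1.0),
        gfr_baseline=gfr_pair[:, 0],
        map_3yr=np.maximum(map_pair[:, 1], 1.0),
        gfr_3yr=gfr_pair[:, 1],
        provenance="synthetic",
    )


def cohort_moments(cohort: ClinicalCohort) -> pd.DataFrame:
    """Exact sample means/SDs per dimension plus pre/post correlations.

    SDs use the sample (ddof=1) convention.  A cohort with any zero-SD
    dimension is flagged degenerate.
    """
    if cohort.n < 2:
        raise ValueError("need at least two patients for moments")
    rows = []
    mat = cohort.matrix()
    for i, dim in enumerate(DIMENSIONS):
        rows.append(
            {
                "dimension": dim,
                "mean": float(np.mean(mat[:, i])),
                "sd": float(np.std(mat[:, i], ddof=1)),
            }
        )
    df = pd.DataFrame(rows)
    degenerate = bool((df["sd"] == 0).any())
    with np.errstate(invalid="ignore", divide="ignore"):
        df.attrs["rho_map"] = float(
            np.corrcoef(cohort.map_baseline, cohort.map_3yr)[0, 1]
        )
        df.attrs["rho_gfr"] = float(
            np.corrcoef(cohort.gfr_baseline, cohort.gfr_3yr)[0, 1]
        )
    df.attrs["degenerate"] = degenerate
    df.attrs["n"] = cohort.n
    return df
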