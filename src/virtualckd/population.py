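"""Virtual-population generation, selection and iterative calibration.

Candidates are parameter-multiplier vectors; each is simulated through the
trial protocol (CKD induction, then 3 years of CCB) to yield four
calibration outputs: MAP and GFR at baseline and at 3 years.  Candidates
within 1 clinical SD of some clinical patient in *all four* standardized
dimensions are eligible; each clinical patient is then greedily assigned
its nearest eligible candidate (Euclidean in standardized space, without
replacement).  Selected parents are re-perturbed (10 children each, +/-5%)
and the loop repeats until the selected population is statistically
indistinguishable from the cohort (all four Mann-Whitney p > 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import CardiorenalModel, Interventions
from .params import ParameterSet, ParameterSpace, default_config
from .pharmacology import TherapySpec
from .protocols import ProtocolSpec, draw_induction_fractions, induce_ckd, run_arm
from .stats_report import similarity_report
from .synthetic_cohort import DIMENSIONS, ClinicalCohort

__all__ = [
    "VirtualPatientRecord",
    "CalibrationResult",
    "sample_parameters",
    "knn_select",
    "refine",
    "simulate_candidates",
    "calibrate",
]

log = logging.getLogger("virtualckd.population")

REFINE_CHILDREN = 10
REFINE_FRACTION = 0.05


@dataclass
class VirtualPatientRecord:
    """One candidate: multipliers, calibration outputs, bookkeeping."""

    patient_id: int
    generation: int
    multipliers: dict[str, float]
    outputs: np.ndarray | None = None  # (4,) in DIMENSIONS order
    valid: bool = True
    eligible: bool = False
    assigned_clinical_id: int | None = None


@dataclass
class CalibrationResult:
    selected: list[VirtualPatientRecord]
    params: ParameterSet            # multiplier vectors of the selected set
    outputs: np.ndarray             # (n_selected, 4)
    induction_fractions: np.ndarray
    generations: int
    log: pd.DataFrame               # per-generation diagnostics
    p_values: dict[str, float]

    @property
    def n(self) -> int:
        return len(self.selected)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for i, rec in enumerate(self.selected):
            row = {
                "patient_id": rec.patient_id,
                "generation": rec.generation,
                "eligible": rec.eligible,
                "assigned_clinical_id": rec.assigned_clinical_id,
            }
            row.update(dict(zip(DIMENSIONS, self.outputs[i])))
            rows.append(row)
        return pd.DataFrame(rows)


def sample_parameters(
    space: ParameterSpace, seed, n: int = 1, generation: int = 0
) -> dict[str, np.ndarray]:
    """Draw ``n`` multiplier vectors with per-patient derived RNG streams.

    Streams are keyed by ``(seed, generation, patient index)`` so any
    patient's draw is reproducible independent of batch size.
    """
    out = {name: np.empty(n) for name in space.names}
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence((seed, generation, i)))
        draw = space.sample(rng, 1)
        for name in space.names:
            out[name][i] = draw[name][0]
    return out


def refine(
    parents: dict[str, np.ndarray],
    seed,
    generation: int,
    n_children: int = REFINE_CHILDREN,
    fraction: float = REFINE_FRACTION,
) -> dict[str, np.ndarray]:
    """Re-perturb each parent ``n_children`` times, multipliers +/-5%.

    Returns children only (callers keep parents alongside); child ``j`` of
    parent ``i`` gets the stream ``(seed, generation, i, j)``.
    """
    names = list(parents)
    n_par = len(parents[names[0]])
    children = {name: np.empty(n_par * n_children) for name in names}
    for i in range(n_par):
        for j in range(n_children):
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, generation, i, j))
            )
            k = i * n_children + j
            for name in names:
                children[name][k] = parents[name][i] * rng.uniform(
                    1.0 - fraction, 1.0 + fraction
                )
    return children


def knn_select(
    virtual_outputs: np.ndarray,
    cohort: ClinicalCohort,
    valid: np.ndarray | None = None,
):
    """Eligibility + greedy nearest assignment in SD-standardized space.

    A virtual record is *eligible* if some clinical patient lies within one
    clinical SD in every one of the four dimensions (Chebyshev <= 1 after
    standardizing each dimension by the cohort SD).  Each clinical patient
    is then assigned its nearest eligible record (Euclidean, ties broken by
    lower index) greedily in order of increasing distance, without
    replacement.

    Returns ``(assignment, eligible)`` where ``assignment`` maps clinical
    index -> virtual index (only for assigned patients) and ``eligible`` is
    a boolean mask over virtual records.

    Raises
    ------
    ValueError
        If no virtual record is eligible (advise another refinement round).
    """
    v = np.asarray(virtual_outputs, dtype=float)
    if v.ndim != 2 or v.shape[1] != 4:
        raise ValueError("virtual outputs must be (n, 4)")
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    c = cohort.matrix()
    sd = c.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("cohort has a zero-SD dimension")
    if valid is None:
        valid = np.all(np.isfinite(v), axis=1)

    vz = v / sd
    cz = c / sd
    # (n_virtual, n_clinical) standardized distances
    diff = vz[:, None, :] - cz[None, :, :]
    cheb = np.max(np.abs(diff), axis=2)
    eligible = valid & np.any(cheb <= 1.0, axis=1)
    if not np.any(eligible):
        raise ValueError(
            "no eligible virtual records within 1 SD of the cohort; "
            "run another refinement round"
        )

    eucl = np.sqrt(np.sum(diff**2, axis=2))
    eucl[~eligible] = np.inf
    # greedy without replacement over all pairs in increasing distance
    pairs = np.argsort(eucl, axis=None, kind="stable")
    assignment: dict[int, int] = {}
    used_virtual: set[int] = set()
    n_virt, n_clin = eucl.shape
    for flat in pairs:
        vi, ci = divmod(int(flat), n_clin)
        if not np.isfinite(eucl[vi, ci]):
            break
        if ci in assignment or vi in used_virtual:
            continue
        assignment[ci] = vi
        used_virtual.add(vi)
        if len(assignment) == n_clin:
            break
    return assignment, eligible


def simulate_candidates(
    multipliers: dict[str, np.ndarray],
    cohort_seed_fractions: np.ndarray,
    therapy: TherapySpec,
    config: dict | None = None,
    protocol_overrides: dict | None = None,
):
    """Run the full protocol for a candidate batch; return (outputs, valid).

    Outputs are the four calibration dimensions (baseline MAP/GFR, 3-year
    MAP/GFR under the therapy).  Candidates whose steady state, induction
    or trial run fails are flagged invalid.
    """
    cfg = config if config is not None else default_config()
    params = ParameterSet(multipliers, config=cfg)
    model = CardiorenalModel(params, config=cfg)
    over = {"cadence_days": 30, "hourly_pd_days": 0}
    over.update(protocol_overrides or {})
    spec = ProtocolSpec.from_config(therapy, cfg, **over)

    state = model.steady_state(Interventions(), verify=True) if params.n == 1 else \
        model.steady_state(Interventions(), verify=False)
    state = induce_ckd(model, state, cohort_seed_fractions, spec)
    result = run_arm(model, state, spec, record=False)

    ep = result.endpoints
    outputs = np.column_stack(
        [
            ep["map_baseline"], ep["gfr_baseline"],
            ep["map_3yr"], ep["gfr_3yr"],
        ]
    )
    valid = result.valid & np.all(np.isfinite(outputs), axis=1)
    valid &= (ep["gfr_baseline"] > 0).to_numpy()
    return outputs, valid, model, state


def calibrate(
    cohort: ClinicalCohort,
    seed: int,
    pool_size: int = 300,
    max_generations: int = 6,
    space: ParameterSpace | None = None,
    config: dict | None = None,
    alpha: float = 0.05,
    protocol_overrides: dict | None = None,
) -> CalibrationResult:
    """Iteratively calibrate a virtual population to the clinical cohort.

    Loop: simulate candidates -> 1-SD/kNN selection -> four-dimension
    Mann-Whitney similarity -> re-perturb selected parents.  Stops when all
    four p-values exceed ``alpha``; raises after ``max_generations``.
    """
    cfg = config if config is not None else default_config()
    space = space if space is not None else ParameterSpace.from_config(cfg)
    therapy = TherapySpec.from_name("ccb", cfg)

    gen_log = []
    candidates = sample_parameters(space, seed, pool_size, generation=0)
    proto_for_draw = ProtocolSpec.from_config(therapy, cfg)
    rng_induction = np.random.default_rng(np.random.SeedSequence((seed, 987)))
    # each candidate owns its CKD-induction fraction; children inherit it
    fractions = draw_induction_fractions(pool_size, rng_induction, proto_for_draw)
    generations_born = np.zeros(pool_size, dtype=int)

    for generation in range(max_generations):
        n_cand = len(candidates[space.names[0]])
        outputs, valid, _, _ = simulate_candidates(
            candidates, fractions, therapy, cfg, protocol_overrides
        )
        log.info(
            "generation %d: %d candidates, %d valid", generation, n_cand,
            int(valid.sum()),
        )
        try:
            assignment, eligible = knn_select(outputs, cohort, valid)
        except ValueError:
            assignment, eligible = {}, np.zeros(n_cand, dtype=bool)
        sel_idx = np.array(sorted(assignment.values()), dtype=int)

        p_values: dict[str, float] = {}
        passed = False
        if sel_idx.size >= 2:
            virt = {d: outputs[sel_idx, k] for k, d in enumerate(DIMENSIONS)}
            clin = {d: getattr(cohort, d) for d in DIMENSIONS}
            results, passed = similarity_report(virt, clin, alpha=alpha)
            p_values = {d: r.p_value for d, r in results.items()}

        gen_log.append(
            {
                "generation": generation,
                "candidates": n_cand,
                "valid": int(valid.sum()),
                "eligible": int(eligible.sum()),
                "selected": int(sel_idx.size),
                **{f"p_{d}": p_values.get(d, np.nan) for d in DIMENSIONS},
                "passed": passed,
            }
        )

        if passed and sel_idx.size == cohort.n:
            sel_mult = {k: v[sel_idx] for k, v in candidates.items()}
            inv_assignment = {v: c for c, v in assignment.items()}
            selected = []
            for vi in sel_idx:
                rec = VirtualPatientRecord(
                    patient_id=int(vi),
                    generation=int(generations_born[vi]),
                    multipliers={k: float(v[vi]) for k, v in candidates.items()},
                    outputs=outputs[vi],
                    valid=bool(valid[vi]),
                    eligible=True,
                    assigned_clinical_id=int(inv_assignment[int(vi)]),
                )
                selected.append(rec)
            return CalibrationResult(
                selected=selected,
                params=ParameterSet(sel_mult, config=cfg),
                outputs=outputs[sel_idx],
                induction_fractions=fractions[sel_idx],
                generations=generation + 1,
                log=pd.DataFrame(gen_log),
                p_values=p_values,
            )

        # refine: children of the selected parents (or of the eligible set
        # when assignment is incomplete), parents retained, induction
        # fraction inherited
        parent_idx = sel_idx if sel_idx.size else np.where(valid)[0][: cohort.n]
        parents = {k: v[parent_idx] for k, v in candidates.items()}
        children = refine(parents, seed, generation + 1)
        candidates = {
            k: np.concatenate([parents[k], children[k]]) for k in parents
        }
        par_frac = fractions[parent_idx]
        fractions = np.concatenate(
            [par_frac, np.repeat(par_frac, REFINE_CHILDREN)]
        )
        par_gen = generations_born[parent_idx]
        generations_born = np.concatenate(
            [par_gen, np.full(par_frac.size * REFINE_CHILDREN, generation + 1)]
        )

    raise RuntimeError(
        "calibration did not converge within "
        f"{max_generations} generations; last p-values: {p_values}"
    )
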