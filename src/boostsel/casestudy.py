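"""Log-linear amino-acid interaction pipeline for phenotype-microarray data.

The design couples a global group effect (sum-to-zero coded, control = -1,
case = +1), per-amino-acid main effects, group-coded per-amino-acid
interactions, and two ridge-penalized random-effect blocks over biological
replicates (overall and group-specific).  The analysis first boosts an
offset model of main effects to a cross-validated stopping iteration and
then runs stability selection over the full learner list, with every
subsample fit starting from the offset-model predictions.

A synthetic fixture generator emulates a typical study layout
(35 replicates x 384 wells, 27 amino-acid incidence annotations) so the
pipeline can be exercised end to end on generated data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .boosting import boost, cv_mstop
from .learners import BaseLearner, linear, ridge_categorical
from .stability import StabSelResult, SubsampleScheme, stabsel

__all__ = [
    "PMRecord",
    "CaseDesign",
    "DEFAULT_AMINO_NAMES",
    "GROUP_CODE",
    "read_pm_long",
    "records_to_frame",
    "write_pm_csv",
    "build_design",
    "gen_fixture",
    "fit_offset_then_stabsel",
    "effect_size_report",
]

GROUP_CODE = {"control": -1.0, "case": 1.0}

#: 20 proteinogenic plus a few non-proteinogenic annotations, 27 in total.
DEFAULT_AMINO_NAMES = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    "Orn", "Cit", "Hyp", "Abu", "Nva", "Nle", "Sar",
)


@dataclass(frozen=True)
class PMRecord:
    """One phenotype-microarray well measurement."""

    replicate_id: str
    group: str
    well_id: str
    value: float
    incidence: tuple[int, ...]

    def __post_init__(self):
        if not self.value > 0:
            raise ValueError(
                f"value must be positive (log is taken), got {self.value}"
            )
        if self.group not in GROUP_CODE:
            raise ValueError(f"unknown group label {self.group!r}")
        if any(i not in (0, 1) for i in self.incidence):
            raise ValueError("incidence entries must be 0 or 1")


@dataclass
class CaseDesign:
    """Learner list and column layout of the case-study design matrix."""

    learners: list[BaseLearner]
    amino_names: tuple[str, ...]
    replicate_levels: tuple[str, ...]
    main_ids: list[str]
    interaction_ids: list[str]

    @property
    def offset_ids(self) -> list[str]:
        """Learners of the stage-1 offset model (all main effects)."""
        return ["group"] + self.main_ids + ["re"]


# ---------------------------------------------------------------------------
# I/O


def records_to_frame(
    records: Sequence[PMRecord], amino_names: Sequence[str]
) -> pd.DataFrame:
    base = pd.DataFrame(
        {
            "id": [r.replicate_id for r in records],
            "group": [r.group for r in records],
            "well": [r.well_id for r in records],
            "value": [r.value for r in records],
        }
    )
    inc = pd.DataFrame(
        [r.incidence for r in records], columns=list(amino_names)
    )
    return pd.concat([base, inc], axis=1)


def write_pm_csv(path, records: Sequence[PMRecord], amino_names: Sequence[str]):
    records_to_frame(records, amino_names).to_csv(path, index=False, float_format="%.10g")


def read_pm_long(path) -> tuple[list[PMRecord], tuple[str, ...]]:
    """Read long-format phenotype-microarray data.

    Expects columns ``id, group, well, value`` followed by one 0/1 column
    per amino-acid annotation.  Returns the validated records and the
    annotation names.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    required = ["id", "group", "well", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    amino_names = tuple(c for c in df.columns if c not in required)
    if not amino_names:
        raise ValueError("no amino-acid incidence columns found")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        value = getattr(row, "value")
        if pd.isna(value) or not value > 0:
            raise ValueError(f"row {i}: non-positive or missing value {value!r}")
        group = getattr(row, "group")
        if group not in GROUP_CODE:
            raise ValueError(f"row {i}: unknown group label {group!r}")
        incidence = tuple(int(getattr(row, a)) for a in amino_names)
        if any(v not in (0, 1) for v in incidence):
            raise ValueError(f"row {i}: incidence entries must be 0/1")
        records.append(
            PMRecord(
                replicate_id=str(getattr(row, "id")),
                group=str(group),
                well_id=str(getattr(row, "well")),
                value=float(value),
                incidence=incidence,
            )
        )
    return records, amino_names


# ---------------------------------------------------------------------------
# design


def build_design(
    records: Sequence[PMRecord], amino_names: Sequence[str]
) -> tuple[CaseDesign, np.ndarray, np.ndarray]:
    """Assemble the design matrix, learner list, and log-response.

    Columns: group code, A incidence columns, A group-coded interaction
    columns (``X(group) * I``), replicate code.  Learner count is
    ``1 + 2A + 2``: group effect, A main effects, A interactions, overall
    and group-specific random effects.
    """
    amino_names = tuple(amino_names)
    if not records:
        raise ValueError("no records")
    A = len(amino_names)
    if any(len(r.incidence) != A for r in records):
        raise ValueError(
            f"incidence length does not match {A} amino-acid names"
        )
    groups = pd.Series([r.group for r in records])
    reps = pd.Series([r.replicate_id for r in records])
    per_group = (
        pd.DataFrame({"g": groups, "r": reps}).groupby("g")["r"].nunique()
    )
    if any(per_group.get(g, 0) < 2 for g in GROUP_CODE):
        raise ValueError("need at least 2 replicates per group")
    rep_in_both = (
        pd.DataFrame({"g": groups, "r": reps}).groupby("r")["g"].nunique()
    )
    if (rep_in_both > 1).any():
        raise ValueError("replicate ids must be unique to one group")

    gcode = np.array([GROUP_CODE[r.group] for r in records])
    inc = np.array([r.incidence for r in records], dtype=float)
    levels = tuple(sorted(reps.unique()))
    rep_code = reps.map({lv: i for i, lv in enumerate(levels)}).to_numpy(float)

    X = np.column_stack([gcode, inc, gcode[:, None] * inc, rep_code])
    y = np.log(np.array([r.value for r in records]))

    rep_col = 1 + 2 * A
    re_df = min(4.0, len(levels) - 1.0)
    main_ids = [f"main:{a}" for a in amino_names]
    inter_ids = [f"int:{a}" for a in amino_names]
    learners = (
        [linear(0, id="group")]
        + [linear(1 + j, id=main_ids[j]) for j in range(A)]
        + [linear(1 + A + j, id=inter_ids[j]) for j in range(A)]
        + [
            ridge_categorical(rep_col, df=re_df, id="re"),
            ridge_categorical(rep_col, df=re_df, id="re_group", scale_column=0),
        ]
    )
    design = CaseDesign(
        learners=learners,
        amino_names=amino_names,
        replicate_levels=levels,
        main_ids=main_ids,
        interaction_ids=inter_ids,
    )
    return design, X, y


# ---------------------------------------------------------------------------
# fixture generator


def gen_fixture(
    n_cases: int = 17,
    n_controls: int = 18,
    wells_per_plate: int = 384,
    amino_names: Sequence[str] = DEFAULT_AMINO_NAMES,
    differential: Mapping[str, float] | None = None,
    re_sd: float = 0.1,
    noise_sd: float = 0.2,
    seed: int = 0,
    intercept: float = 1.0,
    main_effect_sd: float = 0.15,
    case_ids: Sequence[str] | None = None,
    control_ids: Sequence[str] | None = None,
) -> list[PMRecord]:
    """Generate a synthetic phenotype-microarray data set.

    The well layout (which amino acids each well carries, 1-4 annotations
    per well) is drawn once and shared by all replicates, mimicking a fixed
    plate design.  ``differential`` maps amino-acid names to case-minus-
    control shifts on the log scale; half the shift is applied with the
    group code so the group difference equals the full shift.
    """
    differential = dict(differential or {})
    amino_names = tuple(amino_names)
    unknown = set(differential) - set(amino_names)
    if unknown:
        raise ValueError(f"differential names not in amino_names: {sorted(unknown)}")
    if re_sd < 0 or noise_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    if not all(np.isfinite(list(differential.values()) or [0.0])):
        raise ValueError("shifts must be finite")
    rng = np.random.default_rng(seed)
    A = len(amino_names)

    incidence = np.zeros((wells_per_plate, A), dtype=int)
    max_per_well = min(4, A)
    for w in range(wells_per_plate):
        k = int(rng.integers(1, max_per_well + 1))
        incidence[w, rng.choice(A, size=k, replace=False)] = 1
    # every annotation appears in at least one well, as on a designed plate
    for j in np.nonzero(incidence.sum(axis=0) == 0)[0]:
        open_wells = np.nonzero(incidence.sum(axis=1) < max_per_well)[0]
        if open_wells.size == 0:
            raise ValueError(
                "cannot cover every amino-acid annotation: too few wells"
            )
        incidence[rng.choice(open_wells), j] = 1

    beta_main = rng.normal(0.0, main_effect_sd, size=A)
    shift_half = np.array([differential.get(a, 0.0) / 2.0 for a in amino_names])

    case_ids = list(case_ids or (f"case{i + 1:02d}" for i in range(n_cases)))
    control_ids = list(
        control_ids or (f"ctrl{i + 1:02d}" for i in range(n_controls))
    )
    if len(case_ids) != n_cases or len(control_ids) != n_controls:
        raise ValueError("id lists must match the group sizes")
    ids = case_ids + control_ids
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate replicate ids")
    groups = ["case"] * n_cases + ["control"] * n_controls

    records: list[PMRecord] = []
    for rid, grp in zip(ids, groups):
        x_g = GROUP_CODE[grp]
        b_id = rng.normal(0.0, re_sd)
        b_id_g = rng.normal(0.0, re_sd)
        noise = rng.normal(0.0, noise_sd, size=wells_per_plate)
        log_y = (
            intercept
            + incidence @ beta_main
            + b_id
            + x_g * (incidence @ shift_half + b_id_g)
            + noise
        )
        for w in range(wells_per_plate):
            records.append(
                PMRecord(
                    replicate_id=rid,
                    group=grp,
                    well_id=f"W{w + 1:03d}",
                    value=float(np.exp(log_y[w])),
                    incidence=tuple(incidence[w]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# pipeline


def fit_offset_then_stabsel(
    records: Sequence[PMRecord],
    amino_names: Sequence[str] | None = None,
    q: int = 10,
    pfer_max: float = 1.0,
    assumption: str = "unimodal",
    B: int = 50,
    seed: int = 0,
    nu: float = 0.1,
    max_iter: int = 2500,
    offset_mstop: int | str = "cv",
    cv_grid: Sequence[int] = (25, 50, 100, 200, 400, 800),
    cv_folds: int = 5,
):
    """Two-stage analysis: offset model of main effects, then stability
    selection over the full learner list.

    Stage 1 boosts the main-effect learners (group, amino-acid mains,
    overall random effect) on the log response to a cross-validated
    stopping iteration (or a fixed ``offset_mstop``).  Stage 2 runs
    stability selection with all ``1 + 2A + 2`` learners, each subsample
    fit starting from the stage-1 predictions as a fixed offset.
    Subsampling is at the replicate level: all wells of a subject move
    together.

    Returns ``(result, offset_fit, design)``.
    """
    if amino_names is None:
        A = len(records[0].incidence)
        amino_names = DEFAULT_AMINO_NAMES[:A] if A <= len(
            DEFAULT_AMINO_NAMES
        ) else tuple(f"AA{j}" for j in range(A))
    design, X, y = build_design(records, amino_names)
    offset_learners = [
        lr for lr in design.learners if lr.id in set(design.offset_ids)
    ]
    if offset_mstop == "cv":
        m_off = cv_mstop(
            X, y, "gaussian", offset_learners, nu=nu, m_grid=cv_grid,
            folds=cv_folds, seed=seed,
        )
    else:
        m_off = int(offset_mstop)
    offset_fit = boost(X, y, "gaussian", offset_learners, nu=nu, m_stop=m_off)
    offset_pred = offset_fit.predict(X)

    rep_labels = np.array([r.replicate_id for r in records])
    result = stabsel(
        X, y, "gaussian", design.learners,
        q=q, pfer_max=pfer_max,
        scheme=SubsampleScheme("complementary_pairs", B, seed),
        nu=nu, max_iter=max_iter, assumption=assumption,
        offset_value=offset_pred, groups=rep_labels,
    )
    return result, offset_fit, design


def effect_size_report(fit, design: CaseDesign) -> pd.Series:
    """Per-amino-acid group difference (case minus control) on the log
    scale: twice the interaction slope."""
    coef = dict(zip(fit.learner_ids, fit.coefficients))
    out = {}
    for a, lid in zip(design.amino_names, design.interaction_ids):
        c = coef.get(lid)
        out[a] = 0.0 if c is None else 2.0 * float(c[1])
    return pd.Series(out, name="group_difference")
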