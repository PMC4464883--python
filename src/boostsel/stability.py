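"""Stability selection: subsampling, selection frequencies, stable sets.

Two subsampling schemes are supported: plain half-sample subsampling
("mb", B draws) and complementary pairs ("complementary_pairs", B random
splits into two disjoint halves, 2B fits in total).  Each subsample fit
boosts until ``q`` distinct base-learners are selected; relative selection
frequencies over all fits are thresholded to give the stable set, with the
missing member of (q, pi_thr, PFER_max) resolved by the bounds module.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from . import bounds
from .boosting import boost_resolved
from .learners import BaseLearner, resolve_all
from .losses import get_loss

__all__ = [
    "SubsampleScheme",
    "SelectionFrequencies",
    "StabSelResult",
    "draw_subsamples",
    "selection_frequencies",
    "stable_set",
    "stability_paths",
    "stabsel",
    "rethreshold",
]


@dataclass(frozen=True)
class SubsampleScheme:
    """Subsampling scheme: kind, number of draws/pairs, master seed."""

    kind: str = "complementary_pairs"
    B: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("mb", "complementary_pairs"):
            raise ValueError("kind must be 'mb' or 'complementary_pairs'")
        if self.B < 1:
            raise ValueError("B must be >= 1")

    @property
    def n_fits(self) -> int:
        return self.B if self.kind == "mb" else 2 * self.B


def draw_subsamples(n: int, scheme: SubsampleScheme) -> list[np.ndarray]:
    """Draw index sets of size ``floor(n/2)``.

    ``mb`` returns B sets drawn without replacement; ``complementary_pairs``
    returns 2B sets, consecutive sets forming disjoint pairs (for odd n one
    index per pair is left out, re-randomized each pair).  Per-subsample RNG
    streams are spawned from the master seed, so draws are reproducible and
    order-independent.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    half = n // 2
    children = np.random.SeedSequence(scheme.seed).spawn(scheme.B)
    out: list[np.ndarray] = []
    for child in children:
        rng = np.random.default_rng(child)
        if scheme.kind == "mb":
            out.append(np.sort(rng.choice(n, size=half, replace=False)))
        else:
            perm = rng.permutation(n)
            out.append(np.sort(perm[:half]))
            out.append(np.sort(perm[half : 2 * half]))
    return out


@dataclass
class SelectionFrequencies:
    """Relative selection frequencies on the 1/n_fits grid."""

    freqs: dict[str, float]
    n_fits: int

    def __getitem__(self, key: str) -> float:
        return self.freqs[key]

    def sorted(self) -> list[tuple[str, float]]:
        return sorted(self.freqs.items(), key=lambda kv: (-kv[1], kv[0]))

    def as_fractions(self) -> dict[str, Fraction]:
        return {
            k: Fraction(round(v * self.n_fits), self.n_fits)
            for k, v in self.freqs.items()
        }


def selection_frequencies(
    selected_sets: Sequence[set[str] | Sequence[str]],
    universe: Sequence[str],
) -> SelectionFrequencies:
    """Per-learner fraction of subsample fits that selected it."""
    if len(selected_sets) == 0:
        raise ValueError("selected_sets must be non-empty")
    universe = list(universe)
    known = set(universe)
    counts = dict.fromkeys(universe, 0)
    for s in selected_sets:
        s = set(s)
        unknown = s - known
        if unknown:
            raise ValueError(f"selected ids outside universe: {sorted(unknown)}")
        for j in s:
            counts[j] += 1
    n_fits = len(selected_sets)
    return SelectionFrequencies(
        freqs={j: counts[j] / n_fits for j in universe}, n_fits=n_fits
    )


def stable_set(freqs: SelectionFrequencies, pi_thr: float) -> set[str]:
    """Learners selected with frequency at least ``pi_thr`` (inclusive)."""
    if not (0.5 < pi_thr <= 1.0):
        raise ValueError("pi_thr must lie in (0.5, 1]")
    eps = 1e-12
    return {j for j, f in freqs.freqs.items() if f >= pi_thr - eps}


@dataclass
class StabSelResult:
    """Outcome of one stability selection run."""

    frequencies: SelectionFrequencies
    stable: set[str]
    q: int
    pi_thr: float
    pfer_max: float | None
    realized_bound: float
    attainable: bool
    B: int
    scheme: str
    assumption: str
    seed: int
    selected_sets: list[list[str]] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "q": self.q,
            "pi_thr": self.pi_thr,
            "pfer_max": self.pfer_max,
            "realized_bound": self.realized_bound,
            "attainable": self.attainable,
            "B": self.B,
            "scheme": self.scheme,
            "assumption": self.assumption,
            "seed": self.seed,
            "n_fits": self.frequencies.n_fits,
            "stable_set": sorted(self.stable),
            "frequencies": dict(self.frequencies.sorted()),
            "selected_sets": [sorted(s) for s in self.selected_sets],
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "StabSelResult":
        freqs = SelectionFrequencies(dict(d["frequencies"]), int(d["n_fits"]))
        return cls(
            frequencies=freqs,
            stable=set(d["stable_set"]),
            q=int(d["q"]),
            pi_thr=float(d["pi_thr"]),
            pfer_max=d.get("pfer_max"),
            realized_bound=float(d["realized_bound"]),
            attainable=bool(d["attainable"]),
            B=int(d["B"]),
            scheme=d["scheme"],
            assumption=d["assumption"],
            seed=int(d["seed"]),
            selected_sets=[list(s) for s in d.get("selected_sets", [])],
        )


def _resolve_triple(
    p: int,
    q: int | None,
    pi_thr: float | None,
    pfer_max: float | None,
    B: int,
    assumption: str,
) -> tuple[int, float, float | None, float, bool]:
    given = sum(v is not None for v in (q, pi_thr, pfer_max))
    if given != 2:
        raise ValueError(
            "exactly two of (q, pi_thr, pfer_max) must be specified, "
            f"got {given}"
        )
    attainable = True
    if pi_thr is None:
        sol = bounds.solve_cutoff(q, p, pfer_max, B=B, assumption=assumption)
        pi_thr, realized, attainable = sol.pi_thr, sol.realized_bound, sol.attainable
        if not attainable:
            warnings.warn(
                f"PFER_max={pfer_max} not attainable for q={q}, p={p} under "
                f"assumption {assumption!r}; using pi_thr=1 with bound "
                f"{realized:.4g}",
                stacklevel=3,
            )
    elif q is None:
        q = bounds.solve_q(pi_thr, p, pfer_max, B=B, assumption=assumption)
        realized = bounds.pfer_bound(bounds.BoundQuery(q, p, pi_thr, B, assumption))
    else:
        realized = bounds.pfer_bound(bounds.BoundQuery(q, p, pi_thr, B, assumption))
    return q, pi_thr, pfer_max, realized, attainable


def _expand_groups(
    idx_sets: list[np.ndarray], groups: np.ndarray
) -> list[np.ndarray]:
    levels = np.unique(groups)
    out = []
    for s in idx_sets:
        chosen = set(levels[s])
        out.append(np.nonzero(np.isin(groups, list(chosen)))[0])
    return out


def stabsel(
    X,
    y,
    loss,
    learners: Sequence[BaseLearner],
    q: int | None = None,
    pi_thr: float | None = None,
    pfer_max: float | None = None,
    scheme: SubsampleScheme | None = None,
    nu: float = 0.1,
    max_iter: int = 2500,
    assumption: str = "r_concave",
    offset_value: np.ndarray | None = None,
    groups: np.ndarray | None = None,
) -> StabSelResult:
    """Run stability selection with boosting as the base procedure.

    Exactly two of ``(q, pi_thr, pfer_max)`` must be given; the third is
    resolved from the error bound under ``assumption``.  ``offset_value``
    is an optional fixed per-observation offset (sliced per subsample).
    ``groups`` switches subsampling to the level of group labels: all rows
    of a sampled group enter the subsample together.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    loss = get_loss(loss)
    scheme = scheme or SubsampleScheme()
    p = len(learners)
    q, pi_thr, pfer_max, realized, attainable = _resolve_triple(
        p, q, pi_thr, pfer_max, scheme.B, assumption
    )
    if not (1 <= q <= p):
        raise ValueError(f"resolved q={q} must lie in [1, p={p}]")

    resolved = resolve_all(learners, X)
    n_units = X.shape[0] if groups is None else len(np.unique(groups))
    idx_sets = draw_subsamples(n_units, scheme)
    if groups is not None:
        idx_sets = _expand_groups(idx_sets, np.asarray(groups))

    selected_sets: list[list[str]] = []
    for b, rows in enumerate(idx_sets):
        try:
            fit = boost_resolved(
                resolved, y, loss, rows=rows, nu=nu, q=q, max_iter=max_iter,
                offset_value=offset_value,
            )
        except Exception as exc:
            raise RuntimeError(f"subsample fit {b} failed: {exc}") from exc
        selected_sets.append(fit.selected)

    freqs = selection_frequencies(selected_sets, [lr.id for lr in learners])
    return StabSelResult(
        frequencies=freqs,
        stable=stable_set(freqs, pi_thr),
        q=q,
        pi_thr=pi_thr,
        pfer_max=pfer_max,
        realized_bound=realized,
        attainable=attainable,
        B=scheme.B,
        scheme=scheme.kind,
        assumption=assumption,
        seed=scheme.seed,
        selected_sets=selected_sets,
    )


def rethreshold(
    result: StabSelResult,
    pi_thr: float | None = None,
    pfer_max: float | None = None,
    assumption: str | None = None,
) -> StabSelResult:
    """Re-derive the stable set from stored frequencies without re-running
    the subsampling (q is unchanged)."""
    assumption = assumption or result.assumption
    p = len(result.frequencies.freqs)
    if (pi_thr is None) == (pfer_max is None):
        raise ValueError("specify exactly one of pi_thr / pfer_max")
    attainable = True
    if pi_thr is None:
        sol = bounds.solve_cutoff(
            result.q, p, pfer_max, B=result.B, assumption=assumption
        )
        pi_thr, realized, attainable = sol.pi_thr, sol.realized_bound, sol.attainable
    else:
        realized = bounds.pfer_bound(
            bounds.BoundQuery(result.q, p, pi_thr, result.B, assumption)
        )
    return StabSelResult(
        frequencies=result.frequencies,
        stable=stable_set(result.frequencies, pi_thr),
        q=result.q,
        pi_thr=pi_thr,
        pfer_max=pfer_max,
        realized_bound=realized,
        attainable=attainable,
        B=result.B,
        scheme=result.scheme,
        assumption=assumption,
        seed=result.seed,
        selected_sets=result.selected_sets,
    )


def stability_paths(
    X,
    y,
    loss,
    learners: Sequence[BaseLearner],
    nu: float = 0.1,
    scheme: SubsampleScheme | None = None,
    max_m: int = 100,
    offset_value: np.ndarray | None = None,
) -> tuple[list[str], np.ndarray]:
    """Selection frequency of each learner within the first m iterations.

    Returns ``(ids, paths)`` where ``paths[j, m-1]`` is the fraction of
    subsample fits in which learner j was selected at least once within the
    first m iterations; rows are non-decreasing in m.
    """
    if max_m < 1:
        raise ValueError("max_m must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    loss = get_loss(loss)
    scheme = scheme or SubsampleScheme()
    resolved = resolve_all(learners, X)
    idx_sets = draw_subsamples(X.shape[0], scheme)
    ids = [lr.id for lr in learners]
    pos = {lid: j for j, lid in enumerate(ids)}
    first_sel = np.full((len(idx_sets), len(ids)), np.inf)
    for b, rows in enumerate(idx_sets):
        fit = boost_resolved(
            resolved, y, loss, rows=rows, nu=nu, m_stop=max_m,
            offset_value=offset_value,
        )
        for m, lid in enumerate(fit.selection_path, start=1):
            j = pos[lid]
            if first_sel[b, j] == np.inf:
                first_sel[b, j] = m
    ms = np.arange(1, max_m + 1)
    paths = (first_sel[:, :, None] <= ms[None, None, :]).mean(axis=0)
    return ids, paths
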