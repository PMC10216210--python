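"""Artificial Gradient Descent (AGD) hyperparameter search.

AGD is a coordinate-wise, three-candidates-per-hyperparameter search.
Each round evaluates the Cartesian product of per-hyperparameter triples
``(low, mid, high)``; the marginal performance ordering along each
coordinate then decides how that coordinate's triple moves:

* increasing ``P0 < P1 < P2``  -> shift up:      ``(a2, 2*a2, 8*a2)``
* peaked     ``P0 < P1 > P2``  -> refine:        ``((a0+a1)/2, a1, (a1+a2)/2)``
* otherwise (decreasing)       -> shift down:    ``(a0/8, a0/2, a0)``

An oscillation between consecutive rounds (increasing then decreasing or
vice versa) also triggers the refine rule. The filter-bank count ``Nfb``
is searched over an explicit candidate list only, never ratio-updated,
and the stride candidates are expressed as fractions of ``K2`` so the
``S2 <= K2`` constraint holds inside every enumerated combination.

Initial grids mirror the published round-1 plan: ``(Nch, 2*Nch, 8*Nch)``
for the kernel counts and kernel width, ``(K2/8, K2/4, K2)`` for the
stride, and ``{1, 3, 7}`` for ``Nfb``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .model import HyperparamSet

__all__ = [
    "CandidateGrid",
    "RoundResult",
    "AGDState",
    "init_grids",
    "enumerate_round",
    "marginal_trend",
    "next_grid",
    "select_seed_sets",
    "should_stop",
    "hyperparam_correlations",
    "AGDSearch",
]

Trend = Literal["increasing", "peaked", "decreasing"]

RATIO_AXES = ("nk1", "nk2", "k2")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class CandidateGrid:
    """Per-round candidate triples.

    ``axes`` maps ``nk1``/``nk2``/``k2`` to integer ``(low, mid, high)``
    triples and ``s2`` to a triple of K2 fractions; ``nfb_candidates``
    is the explicit filter-bank count list. ``round_index`` counts from 0.
    """

    axes: dict[str, tuple[float, float, float]]
    nfb_candidates: tuple[int, ...]
    round_index: int = 0

    def __post_init__(self) -> None:
        for name, (lo, mid, hi) in self.axes.items():
            if not lo <= mid <= hi:
                raise ValueError(f"axis {name!r} triple {lo, mid, hi} not ordered")
            if lo <= 0:
                raise ValueError(f"axis {name!r} has non-positive candidate {lo}")
        if not self.nfb_candidates:
            raise ValueError("nfb_candidates must be non-empty")

    def is_frozen(self, name: str) -> bool:
        lo, mid, hi = self.axes[name]
        return lo == mid == hi


@dataclass
class RoundResult:
    """Evaluated combinations of one AGD round.

    ``records``: list of ``(HyperparamSet, train_acc_pct, test_acc_pct,
    loss)``.
    """

    round_index: int
    records: list[tuple[HyperparamSet, float, float, float]]

    def __post_init__(self) -> None:
        for hp, tr, te, _ in self.records:
            if not (0 <= tr <= 100 and 0 <= te <= 100):
                raise ValueError(f"accuracy outside [0, 100] for {hp}")

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"nfb": hp.nfb, "nk1": hp.nk1, "nk2": hp.nk2, "k2": hp.k2,
             "s2": hp.s2, "train_acc": tr, "test_acc": te, "loss": lo}
            for hp, tr, te, lo in self.records
        ]
        return pd.DataFrame(rows)

    def best_test_accuracy(self) -> float:
        return max(te for _, _, te, _ in self.records)


@dataclass
class AGDState:
    """Full search history: one grid list + result per round."""

    grids: list[list[CandidateGrid]] = field(default_factory=list)
    results: list[RoundResult] = field(default_factory=list)
    selections: list[list[HyperparamSet]] = field(default_factory=list)
    trends: list[dict[str, dict[str, Trend]]] = field(default_factory=list)
    stopped: bool = False

    def to_dict(self) -> dict:
        return {
            "rounds": [
                {
                    "round": r.round_index,
                    "grids": [
                        {"axes": {k: list(v) for k, v in g.axes.items()},
                         "nfb_candidates": list(g.nfb_candidates)}
                        for g in self.grids[i]
                    ],
                    "records": [
                        {"nfb": hp.nfb, "nk1": hp.nk1, "nk2": hp.nk2,
                         "k2": hp.k2, "s2": hp.s2, "train_acc": tr,
                         "test_acc": te, "loss": lo}
                        for hp, tr, te, lo in r.records
                    ],
                    "selected": [
                        {"nfb": hp.nfb, "nk1": hp.nk1, "nk2": hp.nk2,
                         "k2": hp.k2, "s2": hp.s2}
                        for hp in (self.selections[i]
                                   if i < len(self.selections) else [])
                    ],
                }
                for i, r in enumerate(self.results)
            ],
            "stopped": self.stopped,
        }


def init_grids(
    n_channels: int,
    nfb_candidates: Sequence[int] = (1, 3, 7),
    s2_ratios: tuple[float, float, float] = (1 / 8, 1 / 4, 1.0),
) -> CandidateGrid:
    """Round-0 grid: ``(Nch, 2*Nch, 8*Nch)`` kernel/width triples,
    K2-fraction stride candidates, explicit ``Nfb`` list."""
    if n_channels < 1:
        raise ValueError("n_channels must be positive")
    base = (float(n_channels), 2.0 * n_channels, 8.0 * n_channels)
    axes: dict[str, tuple[float, float, float]] = {
        "nk1": base, "nk2": base, "k2": base, "s2": s2_ratios,
    }
    return CandidateGrid(axes=axes, nfb_candidates=tuple(int(v) for v in nfb_candidates))


def enumerate_round(
    grid: CandidateGrid, nfft: int | None = None
) -> tuple[list[HyperparamSet], int]:
    """Cartesian product of the grid's triples as concrete HyperparamSets.

    The stride fraction resolves against each combination's (possibly
    NFFT-clamped) ``K2``; fractions above 1 make a combination invalid.
    Returns ``(combinations, n_removed)``; raises if every combination
    is invalid.
    """
    combos: list[HyperparamSet] = []
    removed = 0
    # a frozen/collapsed axis contributes one candidate, not three
    axis_values = [
        tuple(dict.fromkeys(grid.axes[a])) for a in ("nk1", "nk2", "k2", "s2")
    ]
    nfb_values = tuple(dict.fromkeys(grid.nfb_candidates))
    for nfb, nk1, nk2, k2, s2_ratio in itertools.product(
        nfb_values, *axis_values
    ):
        k2_eff = int(k2)
        if nfft is not None:
            k2_eff = min(k2_eff, 2 * nfft * nfb)
        s2 = max(_round_half_up(s2_ratio * k2_eff), 1)
        if s2 > k2_eff:
            removed += 1
            continue
        combos.append(HyperparamSet(nfb=int(nfb), nk1=int(nk1), nk2=int(nk2),
                                    k2=k2_eff, s2=s2))
    if not combos:
        raise ValueError(
            f"grid produced no valid combination ({removed} removed by the "
            f"S2 <= K2 / K2 <= 2*NFFT*Nfb clamps)"
        )
    return combos, removed


def marginal_trend(
    performances: Sequence[float],
) -> Trend:
    """Classify the (P_low, P_mid, P_high) ordering along one coordinate.

    Strictly rising -> ``increasing``; strictly falling -> ``decreasing``;
    a peak or any tie at the top -> ``peaked`` (ties refine rather than
    shift, the conservative choice). A valley falls through to
    ``decreasing``.
    """
    p0, p1, p2 = performances
    if p0 < p1 < p2:
        return "increasing"
    if p0 <= p1 and p1 >= p2:
        return "peaked"
    return "decreasing"


def trend_from_results(
    result: RoundResult, grid: CandidateGrid, axis: str, anchor: HyperparamSet,
    nfft: int | None = None,
) -> Trend:
    """Marginal trend of ``axis`` around ``anchor``, looked up in ``result``.

    The three combinations differing from the anchor only in ``axis``
    must all have been evaluated; their test accuracies feed
    :func:`marginal_trend`.
    """
    perfs = []
    by_hp = {}
    for hp, _, te, _ in result.records:
        by_hp.setdefault(hp, te)
    for value in grid.axes[axis]:
        fields = {"nfb": anchor.nfb, "nk1": anchor.nk1, "nk2": anchor.nk2,
                  "k2": anchor.k2, "s2": anchor.s2}
        if axis == "s2":
            s2 = max(_round_half_up(value * anchor.k2), 1)
            fields["s2"] = min(s2, anchor.k2)
        elif axis == "k2":
            v = int(value)
            if nfft is not None:
                v = min(v, 2 * nfft * anchor.nfb)
            fields["k2"] = v
            # stride candidates are K2 fractions: rescale the anchor's
            # stride with the probed width so the probe matches what the
            # enumeration actually evaluated
            ratio = anchor.s2 / anchor.k2
            fields["s2"] = min(max(_round_half_up(ratio * v), 1), v)
        else:
            fields[axis] = int(value)
        probe = HyperparamSet(**fields)
        if probe not in by_hp:
            raise KeyError(
                f"combination {probe} (axis {axis!r} sweep around the anchor) "
                f"was not evaluated in round {result.round_index}"
            )
        perfs.append(by_hp[probe])
    return marginal_trend(perfs)


def next_grid(
    triple: tuple[float, float, float],
    trend: Trend,
    prev_trend: Trend | None = None,
    *,
    integer: bool = True,
    upper: float | None = None,
) -> tuple[float, float, float]:
    """Apply the per-coordinate update rule to one candidate triple.

    ``increasing -> (a2, 2*a2, 8*a2)``; ``peaked`` (or an
    increasing/decreasing oscillation against ``prev_trend``) ->
    ``((a0+a1)/2, a1, (a1+a2)/2)``; ``decreasing -> (a0/8, a0/2, a0)``.
    Integer axes round half-up to >= 1 and enforce strict ordering by
    nudging collisions; if the upper clamp collapses the triple the
    coordinate is returned fully collapsed (callers treat it as frozen).
    """
    a0, a1, a2 = triple
    oscillated = prev_trend is not None and {trend, prev_trend} == {
        "increasing", "decreasing"
    }
    if trend == "peaked" or oscillated:
        new = ((a0 + a1) / 2, a1, (a1 + a2) / 2)
    elif trend == "increasing":
        new = (a2, 2 * a2, 8 * a2)
    else:
        new = (a0 / 8, a0 / 2, a0)

    if integer:
        lo, mid, hi = (max(_round_half_up(v), 1) for v in new)
        if mid <= lo:
            mid = lo + 1
        if hi <= mid:
            hi = mid + 1
        if upper is not None and hi > upper:
            lo, mid, hi = (min(v, upper) for v in (lo, mid, hi))
            if not lo < mid < hi:  # clamp collapsed the ordering
                return (upper, upper, upper)
        return (float(lo), float(mid), float(hi))
    lo, mid, hi = new
    if upper is not None:
        lo, mid, hi = (min(v, upper) for v in (lo, mid, hi))
    return (lo, mid, hi)


def select_seed_sets(
    result: RoundResult, top_m: int = 2,
    chooser: Callable[[pd.DataFrame], Sequence[int]] | None = None,
) -> list[HyperparamSet]:
    """Pick the seed sets for the next round.

    Deterministic ranking: test accuracy desc, then train accuracy desc,
    then loss asc, then enumeration order. ``chooser`` (the manual
    override) receives the ranked table and returns row positions.
    """
    order = sorted(
        range(len(result.records)),
        key=lambda i: (
            -result.records[i][2], -result.records[i][1], result.records[i][3], i
        ),
    )
    frame = result.as_frame().iloc[order].reset_index(drop=True)
    if chooser is not None:
        picks = list(chooser(frame))
        return [result.records[order[p]][0] for p in picks]
    if top_m > len(order):
        import warnings

        warnings.warn(
            f"requested {top_m} seed sets but only {len(order)} evaluated",
            stacklevel=2,
        )
    return [result.records[i][0] for i in order[:top_m]]


def should_stop(best_per_round: Sequence[float], tol_pct: float = 1.0) -> bool:
    """Stop when the best test accuracy improved by < ``tol_pct`` points
    between the last two completed rounds (needs >= 2 rounds)."""
    if len(best_per_round) < 2:
        return False
    return (best_per_round[-1] - best_per_round[-2]) < tol_pct


def hyperparam_correlations(
    results: RoundResult | Sequence[RoundResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of each hyperparameter with performance.

    Returns ``(correlations, pairwise)``. ``correlations`` has one row
    per hyperparameter and columns ``test_acc``/``train_acc``/``loss``;
    zero-variance hyperparameters get NaN (undefined, not 0).
    ``pairwise`` is the evaluated table with test accuracy min-max
    normalized to [0, 1] (column ``test_acc_norm``).
    """
    if isinstance(results, RoundResult):
        results = [results]
    frame = pd.concat([r.as_frame() for r in results], ignore_index=True)
    if len(frame) < 3:
        raise ValueError("need at least 3 evaluated combinations")
    hp_cols = ["nfb", "nk1", "nk2", "k2", "s2"]
    perf_cols = ["test_acc", "train_acc", "loss"]
    corr = pd.DataFrame(index=hp_cols, columns=perf_cols, dtype=float)
    for h in hp_cols:
        x = frame[h].to_numpy(dtype=float)
        for p in perf_cols:
            y = frame[p].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                corr.loc[h, p] = np.nan
            else:
                corr.loc[h, p] = float(np.corrcoef(x, y)[0, 1])
    pairwise = frame.copy()
    lo, hi = frame["test_acc"].min(), frame["test_acc"].max()
    span = hi - lo
    pairwise["test_acc_norm"] = (
        (frame["test_acc"] - lo) / span if span > 0 else 0.0
    )
    return corr, pairwise


class AGDSearch:
    """Driver running AGD rounds against a pluggable objective.

    Parameters
    ----------
    objective : callable
        ``objective(hp: HyperparamSet) -> (train_acc_pct, test_acc_pct,
        loss)``. In the decoder workflow this trains one FB-CCNN per
        combination on a designated subject with a shared seed; any
        cheaper surrogate works for algorithm studies.
    n_channels : int
        Sets the round-0 triples.
    nfft : int or None
        Enables the ``K2 <= 2*NFFT*Nfb`` clamp during enumeration.
    max_rounds : int
        Upper bound on rounds (the published workflow stopped at 2).
    top_m : int
        Seed sets carried into each refinement round.
    tol_pct : float
        Stopping tolerance on best-test-accuracy improvement.
    update_axes : sequence of str
        Coordinates refined after round 0 (default all of nk1, nk2, k2,
        s2).

    Attributes
    ----------
    state_ : AGDState
        Full per-round history.
    best_hp_, best_performance_ : winning combination over all rounds.
    """

    def __init__(self, objective, n_channels: int = 8, *,
                 nfft: int | None = None, nfb_candidates: Sequence[int] = (1, 3, 7),
                 max_rounds: int = 2, top_m: int = 2, tol_pct: float = 1.0,
                 update_axes: Sequence[str] = ("nk1", "nk2", "k2", "s2")):
        self.objective = objective
        self.n_channels = n_channels
        self.nfft = nfft
        self.nfb_candidates = tuple(nfb_candidates)
        self.max_rounds = max_rounds
        self.top_m = top_m
        self.tol_pct = tol_pct
        self.update_axes = tuple(update_axes)

    def _evaluate(self, grids: list[CandidateGrid], round_index: int) -> RoundResult:
        records = []
        seen: set[HyperparamSet] = set()
        for grid in grids:
            combos, _ = enumerate_round(grid, nfft=self.nfft)
            for hp in combos:
                if hp in seen:
                    continue
                seen.add(hp)
                tr, te, lo = self.objective(hp)
                records.append((hp, float(tr), float(te), float(lo)))
        return RoundResult(round_index=round_index, records=records)

    def _refine(self, grid: CandidateGrid, result: RoundResult,
                seed: HyperparamSet,
                prev_trends: dict[str, Trend] | None) -> tuple[CandidateGrid, dict]:
        axes: dict[str, tuple[float, float, float]] = {}
        trends: dict[str, Trend] = {}
        for axis in ("nk1", "nk2", "k2", "s2"):
            triple = grid.axes[axis]
            if axis not in self.update_axes or grid.is_frozen(axis):
                axes[axis] = triple
                continue
            trend = trend_from_results(result, grid, axis, seed, nfft=self.nfft)
            trends[axis] = trend
            prev = (prev_trends or {}).get(axis)
            if axis == "s2":
                axes[axis] = next_grid(triple, trend, prev, integer=False,
                                       upper=1.0)
            else:
                upper = (2 * self.nfft * seed.nfb
                         if (self.nfft is not None and axis == "k2") else None)
                axes[axis] = next_grid(triple, trend, prev, upper=upper)
        return (
            CandidateGrid(axes=axes, nfb_candidates=(seed.nfb,),
                          round_index=grid.round_index + 1),
            trends,
        )

    def fit(self) -> "AGDSearch":
        state = AGDState()
        grids = [init_grids(self.n_channels, self.nfb_candidates)]
        prev_trends: list[dict[str, Trend]] = [{}]
        best_per_round: list[float] = []
        for r in range(self.max_rounds):
            state.grids.append(grids)
            result = self._evaluate(grids, r)
            state.results.append(result)
            best_per_round.append(result.best_test_accuracy())
            seeds = select_seed_sets(result, top_m=self.top_m)
            state.selections.append(seeds)
            if should_stop(best_per_round, self.tol_pct):
                state.stopped = True
                break
            if r + 1 >= self.max_rounds:
                break
            new_grids, new_trends, trend_log = [], [], {}
            for gi, seed in enumerate(seeds):
                grid = grids[min(gi, len(grids) - 1)]
                g2, tr = self._refine(grid, result, seed,
                                      prev_trends[min(gi, len(prev_trends) - 1)])
                new_grids.append(g2)
                new_trends.append(tr)
                trend_log[f"seed_{gi}"] = tr
            state.trends.append(trend_log)
            grids, prev_trends = new_grids, new_trends
        self.state_ = state
        best = max(
            ((hp, tr, te, lo) for res in state.results
             for hp, tr, te, lo in res.records),
            key=lambda rec: rec[2],
        )
        self.best_hp_, self.best_performance_ = best[0], best[2]
        return self
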