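"""Recruitment Markov chain: transition matrices and equilibrium diagnostics.

Because RDS seeds are a convenience sample, the composition of early waves
reflects the seeds rather than the target population.  Modelling recruitment
as a Markov chain on attribute categories — S[i, j] is the probability that
a recruiter in group i enrols a recruit in group j — the sample composition
converges across waves to the chain's stationary vector E (the
*equilibrium*).  The number of waves needed for the seed composition to come
within a tolerance of E is the standard diagnostic for how many early waves
to discard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import DegenerateAttributeError, InputError, NonErgodicError
from .recruitment import RecruitmentForest

DEFAULT_TOLERANCE = 0.02  # the conventional 2% "reached equilibrium" band


@dataclass
class TransitionMatrix:
    """Row-stochastic group-to-group recruitment matrix.

    ``counts[i, j]`` is the number of recruiter->recruit pairs from group
    ``groups[i]`` to group ``groups[j]``; ``S`` is ``counts`` row-normalised.
    Rows whose recruiter group produced no recruits are listed in
    ``unobserved_rows`` and left as zero rows rather than imputed.
    """

    groups: list[str]
    S: np.ndarray
    counts: np.ndarray
    n_pairs_used: int = 0
    n_pairs_dropped: int = 0
    unobserved_rows: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "groups": self.groups,
            "counts": self.counts.tolist(),
            "S": self.S.tolist(),
            "n_pairs_used": self.n_pairs_used,
            "n_pairs_dropped": self.n_pairs_dropped,
            "unobserved_rows": self.unobserved_rows,
        }


@dataclass
class EquilibriumResult:
    """Stationary composition and waves needed to reach it from ``start``."""

    groups: list[str]
    stationary: np.ndarray
    waves_needed: int
    tolerance: float
    trajectory: list[np.ndarray]

    def to_dict(self) -> dict:
        return {
            "groups": self.groups,
            "stationary": self.stationary.tolist(),
            "waves_needed": self.waves_needed,
            "tolerance": self.tolerance,
            "trajectory": [t.tolist() for t in self.trajectory],
        }


def estimate_transition_matrix(
    forest: RecruitmentForest, attribute: str
) -> TransitionMatrix:
    """Count recruiter->recruit pairs by attribute category and row-normalise.

    Pairs where either end lacks the attribute are dropped and tallied in
    ``n_pairs_dropped``.  Raises :class:`DegenerateAttributeError` when fewer
    than two categories are observed among the used pairs.
    """
    pairs = []
    dropped = 0
    for u, v in forest.graph.edges:
        a = forest.records[u].attributes.get(attribute)
        b = forest.records[v].attributes.get(attribute)
        if a is None or b is None:
            dropped += 1
        else:
            pairs.append((a, b))
    groups = sorted({g for p in pairs for g in p})
    if len(groups) < 2:
        raise DegenerateAttributeError(
            f"attribute {attribute!r} has {len(groups)} observed categories "
            "among recruiter-recruit pairs; need >= 2"
        )
    idx = {g: i for i, g in enumerate(groups)}
    counts = np.zeros((len(groups), len(groups)), dtype=int)
    for a, b in pairs:
        counts[idx[a], idx[b]] += 1
    row_sums = counts.sum(axis=1)
    S = np.zeros_like(counts, dtype=float)
    nz = row_sums > 0
    S[nz] = counts[nz] / row_sums[nz, None]
    return TransitionMatrix(
        groups=groups,
        S=S,
        counts=counts,
        n_pairs_used=len(pairs),
        n_pairs_dropped=dropped,
        unobserved_rows=[g for g, ok in zip(groups, nz) if not ok],
    )


def _as_matrix(S) -> np.ndarray:
    if isinstance(S, TransitionMatrix):
        if S.unobserved_rows:
            raise NonErgodicError(
                f"rows with no observed recruiters: {S.unobserved_rows}; "
                "cannot compute a stationary distribution without imputing"
            )
        return np.asarray(S.S, dtype=float)
    return np.asarray(S, dtype=float)


def _check_ergodic(S: np.ndarray) -> None:
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise InputError(f"transition matrix must be square, got {S.shape}")
    if np.any(S < -1e-12) or np.any(np.abs(S.sum(axis=1) - 1) > 1e-9):
        raise InputError("transition matrix must be row-stochastic")
    g = nx.DiGraph(
        (i, j) for i in range(S.shape[0]) for j in range(S.shape[1]) if S[i, j] > 0
    )
    g.add_nodes_from(range(S.shape[0]))
    if not nx.is_strongly_connected(g):
        raise NonErgodicError("transition matrix is reducible")
    if not nx.is_aperiodic(g):
        raise NonErgodicError("transition matrix is periodic")


def stationary_distribution(S) -> np.ndarray:
    """Left fixed point E with E @ S = E, E >= 0, sum(E) = 1.

    Solved as the linear system E (S - I) = 0 with the normalisation
    constraint appended; unique for an ergodic (irreducible, aperiodic)
    chain.  Raises :class:`NonErgodicError` otherwise (e.g. the identity
    matrix, which fixes every distribution).
    """
    S = _as_matrix(S)
    _check_ergodic(S)
    k = S.shape[0]
    A = np.vstack([S.T - np.eye(k), np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    E, *_ = np.linalg.lstsq(A, b, rcond=None)
    E = np.clip(E, 0.0, None)
    E /= E.sum()
    if np.max(np.abs(E @ S - E)) > 1e-8:
        raise NonErgodicError("no unique stationary distribution found")
    return E


def power_iteration_stationary(
    S, tol: float = 1e-12, max_iter: int = 100_000
) -> np.ndarray:
    """Stationary vector by repeated left-multiplication (independent route)."""
    S = _as_matrix(S)
    _check_ergodic(S)
    x = np.full(S.shape[0], 1.0 / S.shape[0])
    for _ in range(max_iter):
        nxt = x @ S
        if np.max(np.abs(nxt - x)) < tol:
            return nxt / nxt.sum()
        x = nxt
    raise NonErgodicError("power iteration did not converge")


def waves_to_equilibrium(
    S,
    start,
    tolerance: float = DEFAULT_TOLERANCE,
    max_waves: int = 10_000,
) -> EquilibriumResult:
    """Smallest k with max|start @ S^k - E| <= tolerance, with trajectory.

    ``start`` is typically the seed composition of the attribute (wave 0);
    ``waves_needed`` is then the number of recruitment waves after which the
    expected sample composition is within ``tolerance`` of equilibrium.
    """
    if tolerance <= 0:
        raise InputError(f"tolerance must be > 0, got {tolerance}")
    groups = S.groups if isinstance(S, TransitionMatrix) else [
        str(i) for i in range(np.asarray(S).shape[0])
    ]
    S = _as_matrix(S)
    start = np.asarray(start, dtype=float)
    if start.shape != (S.shape[0],) or np.any(start < 0) or abs(start.sum() - 1) > 1e-9:
        raise InputError("start must be a probability vector matching S")
    E = stationary_distribution(S)
    x = start.copy()
    trajectory = [x.copy()]
    k = 0
    while np.max(np.abs(x - E)) > tolerance:
        if k >= max_waves:
            raise NonErgodicError(f"no convergence within {max_waves} waves")
        x = x @ S
        k += 1
        trajectory.append(x.copy())
    return EquilibriumResult(
        groups=groups,
        stationary=E,
        waves_needed=k,
        tolerance=tolerance,
        trajectory=trajectory,
    )


def composition(forest: RecruitmentForest, attribute: str, wave: int = 0) -> tuple[list[str], np.ndarray]:
    """Attribute composition of a given wave (default: the seeds, wave 0)."""
    values = [
        forest.records[pid].attributes[attribute]
        for pid in forest.participants_at_wave(wave)
        if attribute in forest.records[pid].attributes
    ]
    if not values:
        raise InputError(f"no observations of {attribute!r} at wave {wave}")
    groups = sorted(set(values))
    vec = np.array([values.count(g) for g in groups], dtype=float)
    return groups, vec / vec.sum()


def equilibrium_report(
    forest: RecruitmentForest,
    attribute: str,
    tolerance: float = DEFAULT_TOLERANCE,
    start_wave: int = 0,
) -> dict:
    """Transition matrix + equilibrium diagnostic for one attribute, as JSON-able dict.

    The start composition is taken from ``start_wave`` (seeds by default;
    wave 1 is the common alternative when seeds are too few).  Categories
    present in the start composition but absent from the pair-based matrix
    (or vice versa) are aligned on the matrix's group list, renormalising.
    """
    tm = estimate_transition_matrix(forest, attribute)
    groups, comp = composition(forest, attribute, wave=start_wave)
    start = np.zeros(len(tm.groups))
    for g, p in zip(groups, comp):
        if g in tm.groups:
            start[tm.groups.index(g)] = p
    if start.sum() == 0:
        raise InputError(
            f"start composition for {attribute!r} shares no categories with "
            "the transition matrix"
        )
    start /= start.sum()
    eq = waves_to_equilibrium(tm, start, tolerance=tolerance)
    return {"attribute": attribute, "transition": tm.to_dict(), **eq.to_dict()}
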