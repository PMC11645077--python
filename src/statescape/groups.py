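"""Paired-state group analysis: per-subject state profiles, usage rates,
occurrence sets, per-state energy t-tests with Bonferroni control, and
complementary paired-state summaries.

Each subject contributes a fitted pairwise-MEM energy table and an
empirical state distribution; group differences are then assessed state by
state on the model energies (a low-variance per-subject summary of how
strongly that subject's dynamics favour the state).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as st

from .ising import MEMParameters, energies as _energies, fit_many
from .signals import StateDistribution, state_label, empirical_distribution

__all__ = [
    "SubjectProfile",
    "build_profiles",
    "usage_rate_partition",
    "occurrence_sets",
    "energy_ttest_per_state",
    "bonferroni",
    "identify_paired_states",
    "paired_state_frequencies",
]


@dataclass
class SubjectProfile:
    """One subject's empirical distribution, fitted model and energy table."""

    subject_id: str
    group: str  # "control" | "patient"
    empirical: StateDistribution
    params: MEMParameters
    energies: np.ndarray

    @property
    def n_rois(self) -> int:
        return self.params.n_rois


def _check_common_n(profiles) -> int:
    if not profiles:
        raise ValueError("no profiles given")
    n = profiles[0].n_rois
    if any(p.n_rois != n for p in profiles):
        raise ValueError("profiles have inconsistent N")
    return n


def build_profiles(cohort, lr: float = 0.1, tol: float = 1e-8,
                   max_iter: int = 500_000, l2: float = 0.0) -> list[SubjectProfile]:
    """Fit one pairwise MEM per subject of a synthetic cohort (batched)."""
    dists = [empirical_distribution(s.states) for s in cohort.subjects]
    fitted = fit_many(dists, lr=lr, tol=tol, max_iter=max_iter, l2=l2)
    return [
        SubjectProfile(s.subject_id, s.group, d, p, _energies(p))
        for s, d, p in zip(cohort.subjects, dists, fitted)
    ]


def usage_rate_partition(profiles, threshold: float = 0.05, band: float = 0.005):
    """Split states by their cross-subject mean visit rate vs a threshold.

    Returns a dict with keys ``"below"``, ``"near"`` and ``"above"``: states
    whose mean empirical probability is below ``threshold - band``, within
    ``+-band`` of the threshold, or above ``threshold + band``.  The 5%
    level is the conventional cut for "visited" vs rarely visited states.
    """
    _check_common_n(profiles)
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    rates = np.mean([p.empirical.probs for p in profiles], axis=0)
    below = set(np.flatnonzero(rates < threshold - band).tolist())
    near = set(np.flatnonzero(np.abs(rates - threshold) <= band).tolist())
    above = set(np.flatnonzero(rates > threshold + band).tolist())
    return {"below": below, "near": near, "above": above, "rates": rates}


def occurrence_sets(profiles):
    """States visited only by patients, only by controls, or by both.

    A state "appears" in a group when at least one subject of that group has
    nonzero empirical probability for it.
    """
    _check_common_n(profiles)
    seen = {"control": set(), "patient": set()}
    for p in profiles:
        if p.group not in seen:
            raise ValueError(f"unknown group {p.group!r}")
        seen[p.group] |= set(np.flatnonzero(p.empirical.probs > 0).tolist())
    if not any(p.group == "control" for p in profiles) or not any(
        p.group == "patient" for p in profiles
    ):
        raise ValueError("both groups must be present")
    patient_only = seen["patient"] - seen["control"]
    control_only = seen["control"] - seen["patient"]
    shared = seen["patient"] & seen["control"]
    return patient_only, control_only, shared


def energy_ttest_per_state(profiles, states=None, equal_var: bool = False) -> pd.DataFrame:
    """Two-sample t-test of per-subject state energies, patient vs control.

    Welch (unequal variances) by default.  States with zero variance in both
    groups get ``p = NaN`` and are flagged in the ``degenerate`` column.
    """
    n = _check_common_n(profiles)
    if states is None:
        states = range(1 << n)
    states = sorted(int(k) for k in states)
    e_ctrl = np.array([p.energies for p in profiles if p.group == "control"])
    e_pat = np.array([p.energies for p in profiles if p.group == "patient"])
    if len(e_ctrl) < 2 or len(e_pat) < 2:
        raise ValueError("need >= 2 subjects per group")
    rows = []
    for k in states:
        a, b = e_pat[:, k], e_ctrl[:, k]  # patient minus control
        degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
        if degenerate:
            t, p = (0.0, np.nan) if np.isclose(a.mean(), b.mean()) else (np.inf, 0.0)
        else:
            t, p = st.ttest_ind(a, b, equal_var=equal_var)
        rows.append({
            "state": k, "label": state_label(k, n), "t": float(t), "p": float(p),
            "mean_control": float(b.mean()), "mean_patient": float(a.mean()),
            "degenerate": bool(degenerate),
        })
    return pd.DataFrame(rows)


def bonferroni(p_values, m: int | None = None, alpha: float = 0.05):
    """Bonferroni adjustment: ``p_adj = min(1, m * p)``.

    ``m`` defaults to the number of tests; it may exceed it (e.g. a global
    candidate count) but never be smaller.  Returns (adjusted, significant)
    where significance means raw ``p < alpha / m``.
    """
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size or m <= 0:
        raise ValueError(f"m={m} must be >= number of p-values and positive")
    adjusted = np.minimum(1.0, m * p)
    with np.errstate(invalid="ignore"):
        significant = p < alpha / m
    return adjusted, significant


def _hamming(a: int, b: int) -> int:
    return bin(a ^ b).count("1")


def _matching_cost(pairs) -> tuple[int, list]:
    return sum(_hamming(a, b) for a, b in pairs), sorted(pairs)


def identify_paired_states(significant, rule: str = "min_hamming", pairs=None):
    """Group significant states into complementary pairs.

    ``rule="min_hamming"`` finds the pairing minimising the total Hamming
    distance between activation maps (exhaustive over matchings for up to 12
    states, greedy beyond), deterministic via lexicographic tie-break;
    ``rule="explicit"`` accepts a user-supplied pairing.  With an odd number
    of states the unpaired leftover is returned, never dropped silently.

    Returns ``(pairs, leftover)`` where pairs is a list of (low, high) state
    index tuples and leftover is a possibly empty list of unpaired states.
    """
    states = sorted(int(k) for k in significant)
    if rule == "explicit":
        if pairs is None:
            raise ValueError("rule='explicit' requires pairs")
        pairs = [tuple(sorted(map(int, p))) for p in pairs]
        used = [s for p in pairs for s in p]
        if len(set(used)) != len(used):
            raise ValueError("explicit pairing reuses a state")
        unknown = set(used) - set(states)
        if unknown:
            raise ValueError(f"explicit pairing references unknown states {sorted(unknown)}")
        leftover = sorted(set(states) - set(used))
        return pairs, leftover
    if rule != "min_hamming":
        raise ValueError(f"unknown rule {rule!r}")
    if len(states) < 2:
        raise ValueError("need at least 2 significant states to pair")

    leftover: list[int] = []
    if len(states) % 2:
        # try each leave-one-out set; keep the cheapest (ties -> smaller state)
        best = None
        for omit in states:
            rest = [s for s in states if s != omit]
            cand_pairs, _ = identify_paired_states(rest, rule="min_hamming")
            cost, ordered = _matching_cost(cand_pairs)
            key = (cost, ordered, omit)
            if best is None or key < best[0]:
                best = (key, cand_pairs, [omit])
        return best[1], best[2]

    if len(states) <= 12:
        best = None
        for pairing in _perfect_matchings(states):
            key = _matching_cost(pairing)
            if best is None or key < best:
                best, best_pairs = key, pairing
        return [tuple(p) for p in best_pairs], leftover
    # greedy fallback for large sets: smallest distance first, ties lexicographic
    remaining = set(states)
    out = []
    dists = sorted(
        ((_hamming(a, b), a, b) for a, b in combinations(states, 2))
    )
    for _, a, b in dists:
        if a in remaining and b in remaining:
            out.append((a, b))
            remaining -= {a, b}
    return out, sorted(remaining)


def _perfect_matchings(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for i, partner in enumerate(rest):
        sub = rest[:i] + rest[i + 1:]
        for matching in _perfect_matchings(sub):
            yield [(first, partner)] + matching


def paired_state_frequencies(profiles, pairs) -> pd.DataFrame:
    """Per-subject mean empirical probability of each complementary pair.

    Column ``"a+b"`` (labels of the two states) holds
    ``(p_hat(a) + p_hat(b)) / 2`` per subject; a ``group`` column supports
    boxplot-style group summaries.
    """
    n = _check_common_n(profiles)
    data = {"group": {p.subject_id: p.group for p in profiles}}
    for a, b in pairs:
        name = f"{state_label(a, n)}+{state_label(b, n)}"
        data[name] = {
            p.subject_id: (p.empirical.probs[a] + p.empirical.probs[b]) / 2.0
            for p in profiles
        }
    df = pd.DataFrame(data)
    df.index.name = "subject_id"
    return df
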