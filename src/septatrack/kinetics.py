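"""State lifetimes, competing transition rates, occupancies, Eyring ratios.

For a state A with competing exits to B, C, ... the exit events are
first-order, so the fraction of episodes ending in B equals k_B/k_A and the
rate constants follow from the measured mean lifetime:

    k_B = B / <t_A>,      k_A = 1/<t_A> = Σ k_X.

Lifetimes are estimated by the exponential MLE under right-censoring
(total observed time over the number of uncensored terminations).  Terminal
episode ends — photobleaching, dissociation, end of acquisition — are
treated as right-censored for the lifetime but counted as the "terminal"
outcome in the transition fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

R_GAS = 8.314  # J/mol/K


@dataclass
class TransitionSummary:
    """Per-state kinetics: lifetime, outcome fractions, rates, occupancy."""

    state: str
    mean_lifetime: float                  # s
    sem_lifetime: float                   # s
    n_observed: int
    n_censored: int
    fractions: Dict[str, float] = field(default_factory=dict)
    fraction_se: Dict[str, float] = field(default_factory=dict)
    rates: Dict[str, float] = field(default_factory=dict)     # 1/s
    total_rate: float = 0.0               # 1/s
    occupancy: Optional[float] = None


def estimate_lifetime(durations: Sequence[float],
                      censored: Sequence[bool]) -> tuple:
    """Censoring-aware exponential mean lifetime.

    <t> = (sum of all observed durations) / (number of uncensored episodes);
    s.e.m. = <t>/sqrt(n_uncensored).  Returns (mean, sem, n_obs, n_cens).
    Raises if every episode is censored (the mean is then undefined).
    """
    durations = np.asarray(durations, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    if durations.shape != censored.shape:
        raise ValueError("durations and censored flags must align")
    n_unc = int((~censored).sum())
    if n_unc == 0:
        raise ValueError("no uncensored episodes; lifetime undefined")
    mean = float(durations.sum() / n_unc)
    return mean, mean / math.sqrt(n_unc), n_unc, int(censored.sum())


def transition_fractions(end_causes: Sequence[str]) -> tuple:
    """Multinomial outcome fractions with binomial standard errors.

    ``censored`` endings (acquisition cut the episode) are folded into
    ``terminal``, matching how an experimenter scores unresumed tracks.
    """
    causes = ["terminal" if c == "censored" else c for c in end_causes]
    n = len(causes)
    if n == 0:
        raise ValueError("no episodes")
    fractions, se = {}, {}
    for c in sorted(set(causes)):
        p = causes.count(c) / n
        fractions[c] = p
        se[c] = math.sqrt(p * (1 - p) / n)
    return fractions, se


def transition_rates(fractions: Dict[str, float],
                     mean_lifetime: float) -> tuple:
    """k_X = fraction_X / <t_A> for each outcome; total k_A = 1/<t_A>."""
    if mean_lifetime <= 0:
        raise ValueError("mean lifetime must be positive")
    rates = {k: f / mean_lifetime for k, f in fractions.items()}
    return rates, 1.0 / mean_lifetime


def state_occupancy(segments, n_boot: int = 200,
                    seed: int = 0) -> tuple:
    """Fraction of aggregate observation time spent in each state.

    ``segments`` is a sequence of objects with ``state``, ``duration`` and
    ``track_id`` attributes (ground-truth episodes work too, with any id).
    The s.e.m. is a track-level bootstrap over molecules.
    """
    segs = list(segments)
    if not segs:
        raise ValueError("no segments")
    total = sum(s.duration for s in segs)
    if total <= 0:
        raise ValueError("zero total time")
    states = sorted({s.state for s in segs})
    occ = {st: sum(s.duration for s in segs if s.state == st) / total
           for st in states}
    ids = sorted({getattr(s, "track_id", 0) for s in segs})
    rng = np.random.default_rng(seed)
    boots = {st: [] for st in states}
    by_id = {i: [s for s in segs if getattr(s, "track_id", 0) == i]
             for i in ids}
    for _ in range(n_boot):
        pick = rng.choice(ids, size=len(ids), replace=True)
        chosen = [s for i in pick for s in by_id[i]]
        tt = sum(s.duration for s in chosen)
        if tt <= 0:
            continue
        for st in states:
            boots[st].append(
                sum(s.duration for s in chosen if s.state == st) / tt)
    sem = {st: float(np.std(boots[st], ddof=1)) if len(boots[st]) > 1
           else float("nan") for st in states}
    return occ, sem


def summarize_state(state: str, segments) -> TransitionSummary:
    """Full TransitionSummary for one state from its episode list."""
    segs = [s for s in segments if s.state == state]
    if not segs:
        raise ValueError(f"no segments in state {state!r}")
    mean, sem, n_obs, n_cens = estimate_lifetime(
        [s.duration for s in segs], [s.censored for s in segs])
    fr, se = transition_fractions([s.end_cause for s in segs])
    rates, k_tot = transition_rates(fr, mean)
    return TransitionSummary(state=state, mean_lifetime=mean,
                             sem_lifetime=sem, n_observed=n_obs,
                             n_censored=n_cens, fractions=fr,
                             fraction_se=se, rates=rates, total_rate=k_tot)


# ---------------------------------------------------------------------------
# Semi-Markov stationary occupancy (analytic oracle for the motion model)
# ---------------------------------------------------------------------------

def semi_markov_occupancy(lifetimes: Dict[str, float],
                          exit_fractions: Dict[str, Dict[str, float]],
                          restart_probs: Dict[str, float]) -> Dict[str, float]:
    """Long-run time occupancies of a semi-Markov chain with restarts.

    ``exit_fractions[state]`` maps outcomes (``to_<state>``,
    ``direction_flip`` — which re-enters the same state — and ``terminal``)
    to probabilities.  Terminal events restart the chain from
    ``restart_probs`` (a new molecule arrives).  Occupancy of state s is
    π_s·τ_s normalized, with π the stationary law of the embedded chain.
    """
    states = sorted(lifetimes)
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    M = np.zeros((n, n))
    for s in states:
        for outcome, p in exit_fractions[s].items():
            if outcome == "terminal":
                for s2, q in restart_probs.items():
                    if q > 0:
                        M[idx[s], idx[s2]] += p * q
            elif outcome == "direction_flip":
                M[idx[s], idx[s]] += p
            else:
                M[idx[s], idx[outcome.removeprefix("to_")]] += p
    w, v = np.linalg.eig(M.T)
    pi = np.real(v[:, np.argmax(np.real(w))])
    pi = np.abs(pi) / np.abs(pi).sum()
    occ = pi * np.array([lifetimes[s] for s in states])
    occ /= occ.sum()
    return {s: float(occ[idx[s]]) for s in states}


# ---------------------------------------------------------------------------
# Eyring temperature ratio
# ---------------------------------------------------------------------------

def eyring_rate_ratio(T1: float, T2: float, dH_kJ_mol: float) -> float:
    """Transition-state-theory rate ratio k(T1)/k(T2).

    k1/k2 = (T1/T2)·exp(−(ΔH‡/R)(1/T1 − 1/T2)); the activation entropy
    cancels.  Temperatures in kelvin, ΔH‡ in kJ/mol.
    """
    if T1 <= 0 or T2 <= 0:
        raise ValueError("temperatures must be positive (kelvin)")
    dH = dH_kJ_mol * 1000.0
    return (T1 / T2) * math.exp(-(dH / R_GAS) * (1.0 / T1 - 1.0 / T2))
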