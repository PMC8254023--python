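"""Individual-based stochastic simulation of shelter-selection trials.

The model is a discrete-time Markov chain with synchronous one-second steps:

* at t = 0 every individual is outside;
* each step, every outside individual independently joins the PS with
  probability ``J_ps`` and the CS with ``J_cs`` (type-specific);
* each step, every sheltered individual independently leaves with
  probability ``Q = rho * exp(-sigma*(X-1))``, where ``X`` is the shelter's
  *pooled* occupancy (all types) at the start of the step.

All decisions within a step use the start-of-step state, so the update is
exchangeable across individuals; an individual cannot leave and rejoin in
the same second.

Because per-second probabilities are of order 1e-3 and social retention
makes the leaving probability collapse once aggregates form, the chain is
quiescent at the vast majority of steps.  The kernel therefore simulates the
chain exactly by *quiet-interval skipping*: while the state is unchanged the
number of steps until the next step in which at least one individual acts is
geometric in the per-step no-event probability, and the acting step's joint
outcome is sampled conditioned on at least one change.  This is a lossless
acceleration of the same discrete-time chain (it is not a continuous-time
approximation); tests cross-validate it against a plain per-step stepper and
against the master equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .core_model import CS, PS, GroupComposition, ModelParams, ParameterError

__all__ = [
    "EXPERIMENT_GRID_MIN",
    "TrialRecord",
    "EnsembleSummary",
    "simulate_trial",
    "simulate_ensemble",
    "scan_composition",
    "scan_group_size",
]

#: Recording grid of the experiment: every 10 min for 3 h, plus a 24-h snapshot.
EXPERIMENT_GRID_MIN: tuple[int, ...] = tuple(range(0, 190, 10)) + (1440,)

TYPE_ORDER: tuple[str, str] = ("naive", "conditioned")


# --------------------------------------------------------------------------
# exact chain kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _trunc_binomial(n: int, p: float) -> int:
    """Sample Binomial(n, p) conditioned on the result being >= 1."""
    if p >= 1.0:
        return n
    q = 1.0 - p
    u = np.random.random() * (1.0 - q ** n)
    pmf = n * p * q ** (n - 1)
    cum = pmf
    k = 1
    while cum < u and k < n:
        pmf *= (n - k) / (k + 1.0) * (p / q)
        k += 1
        cum += pmf
    return k


@njit(cache=True)
def _simulate_realizations(theta, mu_ps, rho, sigma, n_init, rec_times, seeds, out):
    """Run len(seeds) independent realizations, recording at rec_times (s).

    out has shape (R, n_rec, K, 3) with the last axis ordered (PS, CS, outside).
    Each realization re-seeds the generator, so realization r is reproducible
    in isolation.
    """
    K = n_init.shape[0]
    n_rec = rec_times.shape[0]
    ngroups = 3 * K
    q_g = np.empty(ngroups)
    p_g = np.empty(ngroups)
    n_g = np.empty(ngroups, dtype=np.int64)
    q_rest = np.empty(ngroups)
    ps = np.empty(K, dtype=np.int64)
    cs = np.empty(K, dtype=np.int64)
    outc = np.empty(K, dtype=np.int64)
    d_ps = np.empty(K, dtype=np.int64)
    d_cs = np.empty(K, dtype=np.int64)

    for r in range(seeds.shape[0]):
        np.random.seed(seeds[r])
        for k in range(K):
            ps[k] = 0
            cs[k] = 0
            outc[k] = n_init[k]
        t = 0
        ri = 0
        while ri < n_rec:
            x_ps = 0
            x_cs = 0
            for k in range(K):
                x_ps += ps[k]
                x_cs += cs[k]
            # groups: [0,K) out-join, [K,2K) PS-leave, [2K,3K) CS-leave
            q_tot = 1.0
            for k in range(K):
                p_g[k] = theta[k]
                n_g[k] = outc[k]
                p_g[K + k] = rho[k] * np.exp(-sigma[k] * (x_ps - 1)) if x_ps >= 1 else 0.0
                n_g[K + k] = ps[k]
                p_g[2 * K + k] = rho[k] * np.exp(-sigma[k] * (x_cs - 1)) if x_cs >= 1 else 0.0
                n_g[2 * K + k] = cs[k]
            for g in range(ngroups):
                if n_g[g] > 0 and p_g[g] > 0.0:
                    q_g[g] = (1.0 - p_g[g]) ** n_g[g]
                else:
                    q_g[g] = 1.0
                q_tot *= q_g[g]
            if q_tot >= 1.0:
                # absorbing for the recording horizon: nothing can change
                while ri < n_rec:
                    for k in range(K):
                        out[r, ri, k, 0] = ps[k]
                        out[r, ri, k, 1] = cs[k]
                        out[r, ri, k, 2] = outc[k]
                    ri += 1
                break
            if q_tot <= 0.0:
                step = 1
            else:
                u = np.random.random()
                while u <= 0.0:
                    u = np.random.random()
                step = 1 + np.int64(np.floor(np.log(u) / np.log(q_tot)))
                if step < 1:
                    step = 1
            t_event = t + step
            while ri < n_rec and rec_times[ri] < t_event:
                for k in range(K):
                    out[r, ri, k, 0] = ps[k]
                    out[r, ri, k, 1] = cs[k]
                    out[r, ri, k, 2] = outc[k]
                ri += 1
            if ri >= n_rec:
                break
            # joint outcome at the event step, conditioned on >= 1 change
            acc = 1.0
            for g in range(ngroups - 1, -1, -1):
                q_rest[g] = acc
                acc *= q_g[g]
            happened = False
            for k in range(K):
                d_ps[k] = 0
                d_cs[k] = 0
            for g in range(ngroups):
                if n_g[g] == 0 or p_g[g] <= 0.0:
                    continue
                if happened:
                    m = np.random.binomial(n_g[g], p_g[g])
                else:
                    denom = 1.0 - q_g[g] * q_rest[g]
                    if denom <= 0.0:
                        continue
                    p_skip = q_g[g] * (1.0 - q_rest[g]) / denom
                    if np.random.random() < p_skip:
                        continue
                    happened = True
                    m = _trunc_binomial(n_g[g], p_g[g])
                if m == 0:
                    continue
                k = g % K
                if g < K:
                    a = np.random.binomial(m, mu_ps[k])
                    d_ps[k] += a
                    d_cs[k] += m - a
                    outc[k] -= m
                elif g < 2 * K:
                    ps[k] -= m
                    outc[k] += m
                else:
                    cs[k] -= m
                    outc[k] += m
            for k in range(K):
                ps[k] += d_ps[k]
                cs[k] += d_cs[k]
            t = t_event


def _type_arrays(composition: GroupComposition):
    labels = [lab for lab in TYPE_ORDER if composition.counts()[lab] > 0]
    if not labels:  # unreachable given GroupComposition validation
        raise ParameterError("empty composition")
    params = [composition.params_by_type[lab] for lab in labels]
    theta = np.array([p.theta for p in params])
    mu_ps = np.array([p.mu_ps for p in params])
    rho = np.array([p.rho for p in params])
    sigma = np.array([p.sigma for p in params])
    n_init = np.array([composition.counts()[lab] for lab in labels], dtype=np.int64)
    return labels, theta, mu_ps, rho, sigma, n_init


def _run_kernel(
    composition: GroupComposition,
    rec_times_s: np.ndarray,
    seeds: np.ndarray,
) -> tuple[list[str], np.ndarray]:
    labels, theta, mu_ps, rho, sigma, n_init = _type_arrays(composition)
    out = np.zeros((seeds.size, rec_times_s.size, len(labels), 3), dtype=np.int64)
    _simulate_realizations(
        theta, mu_ps, rho, sigma, n_init, rec_times_s.astype(np.int64),
        seeds.astype(np.int64), out,
    )
    return labels, out


def _recording_grid(duration: float, record_times_min: Sequence[int] | None) -> np.ndarray:
    if duration < 1:
        raise ValueError("duration must be >= 1 second")
    if record_times_min is None:
        times = [t for t in EXPERIMENT_GRID_MIN if t * 60 <= duration]
        last = int(duration // 60)
        if last * 60 == duration and last not in times:
            times.append(last)
    else:
        times = sorted(set(int(t) for t in record_times_min))
        if any(t < 0 or t * 60 > duration for t in times):
            raise ValueError("recording times must lie within [0, duration]")
    if not times:
        raise ValueError("recording grid is empty")
    return np.asarray(times, dtype=np.int64)


def _realization_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32).astype(np.int64)


# --------------------------------------------------------------------------
# trial- and ensemble-level interfaces
# --------------------------------------------------------------------------

@dataclass
class TrialRecord:
    """Occupancy counts of one trial on the recording grid.

    ``counts`` has shape (n_times, n_types, 3) with the last axis ordered
    (n_ps, n_cs, n_out); ``type_labels`` names the middle axis.
    """

    trial_id: str
    condition: str
    times_min: np.ndarray
    type_labels: list[str]
    counts: np.ndarray
    seed: int

    @property
    def n_total(self) -> int:
        return int(self.counts[0].sum())

    def pooled(self) -> np.ndarray:
        """Counts summed over types: shape (n_times, 3)."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (trial_id, condition, type, time_min, n_ps, n_cs, n_out)."""
        rows = []
        for ti, t in enumerate(self.times_min):
            for ki, lab in enumerate(self.type_labels):
                n_ps, n_cs, n_out = self.counts[ti, ki]
                rows.append((self.trial_id, self.condition, lab, int(t),
                             int(n_ps), int(n_cs), int(n_out)))
        return pd.DataFrame(
            rows, columns=["trial_id", "condition", "type", "time_min",
                           "n_ps", "n_cs", "n_out"],
        )


@dataclass
class EnsembleSummary:
    """Aggregate of independent realizations of one composition.

    ``final_states`` holds the pooled (i, j) occupancy of every realization
    at the last recorded time; per-time means and SEMs are over realizations.
    ``sem_counts`` is None for a single realization (SEM undefined).
    """

    n_realizations: int
    n_total: int
    times_min: np.ndarray
    type_labels: list[str]
    mean_counts: np.ndarray        # (n_times, n_types, 3)
    sem_counts: np.ndarray | None  # same shape, None if n_realizations == 1
    final_states: np.ndarray       # (R, 2) pooled (i, j) at the last time
    metadata: dict = field(default_factory=dict)

    def majority_fractions(self) -> dict[str, float]:
        """Fractions of realizations with a strict PS/CS occupancy majority."""
        i, j = self.final_states[:, 0], self.final_states[:, 1]
        r = self.n_realizations
        return {
            "ps": float((i > j).sum()) / r,
            "cs": float((j > i).sum()) / r,
            "tie": float((i == j).sum()) / r,
        }

    def selection_fractions(self, threshold: float = 0.9) -> dict[str, float]:
        """Fractions with >= threshold of the *sheltered* population in one shelter."""
        i, j = self.final_states[:, 0], self.final_states[:, 1]
        sheltered = i + j
        ok = sheltered > 0
        ps = ok & (i >= threshold * sheltered)
        cs = ok & (j >= threshold * sheltered)
        r = self.n_realizations
        return {"ps": float(ps.sum()) / r, "cs": float(cs.sum()) / r,
                "none": float(r - ps.sum() - cs.sum()) / r}

    def consensus_fraction(self, threshold: float = 0.9, basis: str = "total") -> float:
        """Fraction of realizations with >= threshold of the basis population
        in a single shelter."""
        i, j = self.final_states[:, 0], self.final_states[:, 1]
        big = np.maximum(i, j)
        if basis == "total":
            hit = big >= threshold * self.n_total
        elif basis == "sheltered":
            sheltered = i + j
            hit = (sheltered > 0) & (big >= threshold * sheltered)
        else:
            raise ValueError("basis must be 'total' or 'sheltered'")
        return float(hit.sum()) / self.n_realizations

    def mean_sheltered_fraction(self) -> float:
        """Mean fraction of the population sheltered at the final time."""
        return float(self.final_states.sum(axis=1).mean()) / self.n_total


def simulate_trial(
    composition: GroupComposition,
    duration: float = 86_400,
    seed: int = 0,
    *,
    record_times_min: Sequence[int] | None = None,
    trial_id: str = "trial-0",
    condition: str = "",
) -> TrialRecord:
    """Simulate one trial of the per-second chain; identical seed, identical record."""
    rec = _recording_grid(duration, record_times_min)
    seeds = _realization_seeds(seed, 1)
    labels, out = _run_kernel(composition, rec * 60, seeds)
    return TrialRecord(
        trial_id=trial_id,
        condition=condition,
        times_min=rec,
        type_labels=labels,
        counts=out[0],
        seed=int(seed),
    )


def simulate_trials(
    composition: GroupComposition,
    n_trials: int,
    duration: float = 86_400,
    seed: int = 0,
    *,
    record_times_min: Sequence[int] | None = None,
    condition: str = "",
    trial_prefix: str = "trial",
) -> list[TrialRecord]:
    """Simulate ``n_trials`` independent trials sharing one master seed.

    Trial k uses the k-th stream of the master seed's sequence, so the batch
    equals k separate :func:`simulate_trial` calls with those streams.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rec = _recording_grid(duration, record_times_min)
    seeds = _realization_seeds(seed, n_trials)
    labels, out = _run_kernel(composition, rec * 60, seeds)
    return [
        TrialRecord(
            trial_id=f"{trial_prefix}-{k}",
            condition=condition,
            times_min=rec,
            type_labels=labels,
            counts=out[k],
            seed=int(seeds[k]),
        )
        for k in range(n_trials)
    ]


def simulate_ensemble(
    composition: GroupComposition,
    duration: float = 86_400,
    n_realizations: int = 10_000,
    seed: int = 0,
    *,
    record_times_min: Sequence[int] | None = None,
) -> EnsembleSummary:
    """Aggregate ``n_realizations`` independent trials.

    Realization r uses the r-th stream of a seed sequence spawned from the
    master seed, so the ensemble is the exact concatenation of
    :func:`simulate_trial` runs and two ensembles with the same master seed
    are bitwise identical.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    rec = _recording_grid(duration, record_times_min)
    seeds = _realization_seeds(seed, n_realizations)
    labels, out = _run_kernel(composition, rec * 60, seeds)
    mean = out.mean(axis=0)
    sem = None
    if n_realizations > 1:
        sem = out.std(axis=0, ddof=1) / np.sqrt(n_realizations)
    final = out[:, -1, :, :2].sum(axis=1)
    return EnsembleSummary(
        n_realizations=n_realizations,
        n_total=composition.total,
        times_min=rec,
        type_labels=labels,
        mean_counts=mean,
        sem_counts=sem,
        final_states=final,
        metadata={
            "seed": int(seed),
            "duration_s": float(duration),
            "params_by_type": {
                lab: composition.params_by_type[lab].to_dict()
                for lab in labels
            },
            "composition": composition.counts(),
        },
    )


def _scan_row(summary: EnsembleSummary) -> dict:
    maj = summary.majority_fractions()
    sel = summary.selection_fractions()
    return {
        "ps_majority_frac": maj["ps"],
        "cs_majority_frac": maj["cs"],
        "tie_frac": maj["tie"],
        "ps_selection_frac": sel["ps"],
        "cs_selection_frac": sel["cs"],
        "consensus_frac": summary.consensus_fraction(basis="total"),
        "mean_sheltered_frac": summary.mean_sheltered_fraction(),
    }


def scan_composition(
    total_n: int,
    naive_counts: Iterable[int],
    params_by_type: Mapping[str, ModelParams],
    duration: float = 86_400,
    n_realizations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """PS/CS selection and consensus fractions across group compositions.

    One row per requested naive count (conditioned = total - naive), in the
    requested order.
    """
    naive_counts = list(naive_counts)
    if not naive_counts:
        raise ValueError("naive_counts must not be empty")
    if any(c < 0 or c > total_n for c in naive_counts):
        raise ValueError("each naive count must lie in [0, total_n]")
    children = np.random.SeedSequence(seed).spawn(len(naive_counts))
    rows = []
    for n_naive, child in zip(naive_counts, children):
        comp = GroupComposition(n_naive, total_n - n_naive, params_by_type)
        summary = simulate_ensemble(
            comp, duration, n_realizations,
            seed=int(child.generate_state(1, dtype=np.uint32)[0]),
            record_times_min=[0, int(duration // 60)],
        )
        row = {"n_naive": n_naive, "n_conditioned": total_n - n_naive,
               "prop_conditioned": (total_n - n_naive) / total_n}
        row.update(_scan_row(summary))
        rows.append(row)
    return pd.DataFrame(rows)


def scan_group_size(
    sizes: Iterable[int],
    naive_fraction: float,
    params_by_type: Mapping[str, ModelParams],
    duration: float = 86_400,
    n_realizations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sheltered and consensus fractions versus group size N.

    The condition's composition ratio is preserved by rounding the naive
    count to the nearest integer (ties rounded up); the realized counts are
    reported per row.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("sizes must not be empty")
    if any(n < 1 for n in sizes):
        raise ValueError("group sizes must be >= 1")
    if not (0.0 <= naive_fraction <= 1.0):
        raise ValueError("naive_fraction must lie in [0, 1]")
    children = np.random.SeedSequence(seed).spawn(len(sizes))
    rows = []
    for n, child in zip(sizes, children):
        n_naive = int(np.floor(naive_fraction * n + 0.5))
        comp = GroupComposition(n_naive, n - n_naive, params_by_type)
        summary = simulate_ensemble(
            comp, duration, n_realizations,
            seed=int(child.generate_state(1, dtype=np.uint32)[0]),
            record_times_min=[0, int(duration // 60)],
        )
        row = {"n_total": n, "n_naive": n_naive, "n_conditioned": n - n_naive}
        row.update(_scan_row(summary))
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# plain per-step reference stepper (cross-validation of the kernel)
# --------------------------------------------------------------------------

def _stepwise_final_states(
    composition: GroupComposition,
    duration: int,
    n_realizations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Naive synchronous per-step simulation, vectorized over realizations.

    Returns pooled (i, j) at ``duration`` seconds.  Kept deliberately
    independent of the jump-skipping kernel: it draws the per-step binomials
    literally, one step at a time.
    """
    _, theta, mu_ps, rho, sigma, n_init = _type_arrays(composition)
    K = n_init.size
    R = n_realizations
    outc = np.tile(n_init[:, None], (1, R))
    ps = np.zeros((K, R), dtype=np.int64)
    cs = np.zeros((K, R), dtype=np.int64)
    for _ in range(int(duration)):
        x_ps = ps.sum(axis=0)
        x_cs = cs.sum(axis=0)
        q_ps = np.exp(-np.clip(x_ps - 1, 0, None)[None, :] * sigma[:, None]) * rho[:, None]
        q_cs = np.exp(-np.clip(x_cs - 1, 0, None)[None, :] * sigma[:, None]) * rho[:, None]
        joins = rng.binomial(outc, theta[:, None])
        to_ps = rng.binomial(joins, mu_ps[:, None])
        leave_ps = rng.binomial(ps, q_ps)
        leave_cs = rng.binomial(cs, q_cs)
        ps += to_ps - leave_ps
        cs += (joins - to_ps) - leave_cs
        outc += leave_ps + leave_cs - joins
    return np.stack([ps.sum(axis=0), cs.sum(axis=0)], axis=1)
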