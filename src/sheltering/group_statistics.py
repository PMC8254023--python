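"""Trial-level statistics for replicated group-choice experiments.

All tests operate on long-format trial tables (columns ``trial_id``,
``condition``, ``type``, ``time_min``, ``n_ps``, ``n_cs``, ``n_out``) and
resolve each trial's pooled occupancy per recorded time.  The three bespoke
resampling tests mirror the experimental analysis:

* :func:`resampling_condition_test` — does the total sheltered population of
  one condition lie within the resampled distribution of another?
* :func:`binomial_sociality_test` — is the across-trial variance of the
  focal-shelter count larger than expected for independent (binomial,
  nonsocial) shelter choice?
* :func:`ps_cs_permutation_test` — is the focal shelter preferred, against a
  null that randomly swaps each trial's PS/CS occupancies?

Consensus metrics (winner shelter, settling time ``T_w``, the 90% consensus
flag and the occupancy difference ``N_ps - N_cs``) are computed per trial;
censored ``T_w`` tables and the integer-binned difference histograms are the
exact inputs expected by external survival and bimodality routines, which
are deliberately not reimplemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulator import TrialRecord

__all__ = [
    "ConsensusSummary",
    "TestResult",
    "consensus_metrics",
    "consensus_table",
    "resampling_condition_test",
    "binomial_sociality_test",
    "ps_cs_permutation_test",
    "occupancy_difference_distribution",
]


@dataclass
class ConsensusSummary:
    """Winner, settling time and consensus status of one trial."""

    trial_id: str
    winner: str | None            # "PS", "CS" or None (tie at the final time)
    t_w_min: int | None           # earliest time the winner stays strictly ahead
    t_w_censored: bool
    consensus: bool | None        # None when undefined (no sheltered, basis=sheltered)
    basis: str
    times_min: np.ndarray
    diff: np.ndarray              # pooled n_ps - n_cs per recorded time
    threshold: float = 0.9


@dataclass
class TestResult:
    """Per-time-step outcome of a resampling/permutation test.

    ``table`` has one row per time step with the observed statistic, the
    central-interval bounds of the null distribution, the p-value and the
    significance flag; rows where the test is undefined are flagged in
    ``skipped``.
    """

    name: str
    table: pd.DataFrame
    n_iterations: int
    seed: int
    alpha: float = 0.05
    notes: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# table plumbing
# --------------------------------------------------------------------------

def _pooled(table: pd.DataFrame) -> pd.DataFrame:
    """Per (trial_id, time_min) occupancies summed over behavioural types."""
    required = {"trial_id", "time_min", "n_ps", "n_cs", "n_out"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    g = table.groupby(["trial_id", "time_min"], sort=True)[["n_ps", "n_cs", "n_out"]].sum()
    return g.reset_index()


def _wide(table: pd.DataFrame, column: str) -> pd.DataFrame:
    """trials x times matrix of one pooled count column."""
    pooled = _pooled(table)
    return pooled.pivot(index="trial_id", columns="time_min", values=column)


def _check_shared_grid(*tables: pd.DataFrame) -> np.ndarray:
    grids = [np.sort(t["time_min"].unique()) for t in tables]
    for g in grids[1:]:
        if not np.array_equal(grids[0], g):
            raise ValueError("trial tables do not share a recording time grid")
    return grids[0]


def _two_sided_p(null: np.ndarray, observed: float) -> float:
    lo = np.mean(null <= observed)
    hi = np.mean(null >= observed)
    return float(min(1.0, 2.0 * min(lo, hi)))


# --------------------------------------------------------------------------
# consensus metrics
# --------------------------------------------------------------------------

def consensus_metrics(
    trial: TrialRecord | pd.DataFrame,
    basis: str = "sheltered",
    threshold: float = 0.9,
) -> ConsensusSummary:
    """Winner shelter, ``T_w`` and the consensus flag for a single trial.

    The winner is the shelter with the larger pooled occupancy at the final
    recorded time (a tie means no winner and a censored ``T_w``).  ``T_w`` is
    the earliest recorded time from which the winner is strictly the most
    occupied shelter at every subsequent recorded time; consensus requires at
    least ``threshold`` of the basis population (``sheltered`` or ``total``)
    in a single shelter at the final time.
    """
    if basis not in {"sheltered", "total"}:
        raise ValueError("basis must be 'sheltered' or 'total'")
    if isinstance(trial, TrialRecord):
        times = np.asarray(trial.times_min)
        pooled = trial.pooled()
        trial_id = trial.trial_id
    else:
        pooled_df = _pooled(trial)
        ids = pooled_df["trial_id"].unique()
        if ids.size != 1:
            raise ValueError("consensus_metrics expects a single trial")
        trial_id = str(ids[0])
        pooled_df = pooled_df.sort_values("time_min")
        times = pooled_df["time_min"].to_numpy()
        pooled = pooled_df[["n_ps", "n_cs", "n_out"]].to_numpy()
    ps, cs, out = pooled[:, 0], pooled[:, 1], pooled[:, 2]
    n_total = int(pooled[-1].sum())
    diff = ps - cs

    fin_ps, fin_cs = int(ps[-1]), int(cs[-1])
    if fin_ps > fin_cs:
        winner = "PS"
        ahead = ps > cs
    elif fin_cs > fin_ps:
        winner = "CS"
        ahead = cs > ps
    else:
        winner = None
        ahead = np.zeros(times.size, dtype=bool)

    t_w: int | None = None
    if winner is not None:
        # earliest index from which `ahead` holds at every later recorded time
        behind = np.flatnonzero(~ahead)
        start = behind[-1] + 1 if behind.size else 0
        if start < times.size:
            t_w = int(times[start])
    censored = t_w is None

    big = max(fin_ps, fin_cs)
    sheltered = fin_ps + fin_cs
    consensus: bool | None
    if basis == "total":
        consensus = big >= threshold * n_total
    elif sheltered == 0:
        consensus = None
    else:
        consensus = big >= threshold * sheltered
    return ConsensusSummary(
        trial_id=trial_id,
        winner=winner,
        t_w_min=t_w,
        t_w_censored=censored,
        consensus=consensus,
        basis=basis,
        times_min=times,
        diff=diff,
        threshold=threshold,
    )


def consensus_table(
    table: pd.DataFrame, basis: str = "sheltered", threshold: float = 0.9
) -> pd.DataFrame:
    """Per-trial consensus summary of a whole table (censored T_w rows included).

    The output (columns ``trial_id``, ``winner``, ``t_w_min``, ``censored``,
    ``consensus``) is ready for external survival-analysis routines.
    """
    rows = []
    for tid in table["trial_id"].unique():
        s = consensus_metrics(
            table[table["trial_id"] == tid], basis=basis, threshold=threshold
        )
        rows.append(
            {
                "trial_id": tid,
                "winner": s.winner,
                "t_w_min": s.t_w_min,
                "censored": s.t_w_censored,
                "consensus": s.consensus,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# bespoke resampling tests
# --------------------------------------------------------------------------

def resampling_condition_test(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    n_iter: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Compare the sheltering dynamics of condition A against condition B.

    Per time step, the across-trial mean total sheltered count of A is
    located within the distribution of means of ``n_A`` trials resampled
    (with replacement) from B; significance is a two-sided 5% percentile
    test.

    .. note::
       The procedure treats B's empirical distribution as the reference
       population, so it is exactly calibrated for the null "A's trials are
       draws from B's trials".  Against the broader null that A and B are
       independent samples of one common process it is anti-conservative
       (the reference distribution omits B's own mean uncertainty, inflating
       the type-I rate to roughly ``2*Phi(-1.96/sqrt(1+n_A/n_B))``, about
       14% at 15 vs 19 trials).  Interpret borderline significances
       accordingly.
    """
    grid = _check_shared_grid(table_a, table_b)
    a_sh = _wide(table_a, "n_ps") + _wide(table_a, "n_cs")
    b_sh = _wide(table_b, "n_ps") + _wide(table_b, "n_cs")
    if len(a_sh) < 2 or len(b_sh) < 2:
        raise ValueError("both conditions need at least 2 trials")
    rng = np.random.default_rng(seed)
    rows = []
    for t in grid:
        a_vals = a_sh[t].to_numpy(dtype=float)
        b_vals = b_sh[t].to_numpy(dtype=float)
        idx = rng.integers(0, b_vals.size, size=(n_iter, a_vals.size))
        null_means = b_vals[idx].mean(axis=1)
        obs = float(a_vals.mean())
        lo, hi = np.percentile(null_means, [2.5, 97.5])
        p = _two_sided_p(null_means, obs)
        rows.append(
            {"time_min": int(t), "statistic": obs, "null_lo": lo, "null_hi": hi,
             "p_value": p, "significant": bool(p < 0.05), "skipped": False}
        )
    return TestResult("resampling_condition", pd.DataFrame(rows), n_iter, seed)


def binomial_sociality_test(
    table: pd.DataFrame,
    focal: str = "PS",
    n_iter: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Variance test of the nonsocial (binomial) shelter-choice null.

    Per time step the focal-shelter counts of the trials are compared with
    draws in which each trial's sheltered individuals choose the focal
    shelter independently with the pooled probability
    ``p = (total focal count) / (total sheltered count)``.  Sociality inflates
    the across-trial variance, so the null is rejected one-sidedly when the
    observed variance exceeds the 95th percentile of the simulated variances.
    """
    if focal not in {"PS", "CS"}:
        raise ValueError("focal must be 'PS' or 'CS'")
    ps = _wide(table, "n_ps")
    cs = _wide(table, "n_cs")
    if len(ps) < 2:
        raise ValueError("need at least 2 trials")
    f = ps if focal == "PS" else cs
    sheltered = ps + cs
    rng = np.random.default_rng(seed)
    rows = []
    for t in ps.columns:
        s_t = sheltered[t].to_numpy(dtype=np.int64)
        f_t = f[t].to_numpy(dtype=np.int64)
        tot = int(s_t.sum())
        if tot == 0:
            rows.append({"time_min": int(t), "statistic": np.nan, "null_lo": np.nan,
                         "null_hi": np.nan, "p_value": np.nan, "significant": False,
                         "skipped": True})
            continue
        p_hat = f_t.sum() / tot
        obs_var = float(np.var(f_t, ddof=1))
        sims = rng.binomial(s_t[None, :], p_hat, size=(n_iter, s_t.size))
        sim_var = sims.var(axis=1, ddof=1)
        p = float((1 + np.sum(sim_var >= obs_var)) / (n_iter + 1))
        lo, hi = np.percentile(sim_var, [5.0, 95.0])
        rows.append(
            {"time_min": int(t), "statistic": obs_var, "null_lo": lo, "null_hi": hi,
             "p_value": p, "significant": bool(p < 0.05), "skipped": False}
        )
    return TestResult("binomial_sociality", pd.DataFrame(rows), n_iter, seed,
                      notes={"focal": focal, "one_sided": True})


def ps_cs_permutation_test(
    table: pd.DataFrame,
    focal: str = "PS",
    n_iter: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Shelter-preference test by random PS/CS label swaps.

    Per iteration each trial's (n_ps, n_cs) pair is swapped with probability
    1/2 and the pooled focal-shelter proportion of the sheltered population
    is recomputed; the observed proportion is assessed two-sidedly against
    the central 95% of the permutation distribution.
    """
    if focal not in {"PS", "CS"}:
        raise ValueError("focal must be 'PS' or 'CS'")
    ps = _wide(table, "n_ps")
    cs = _wide(table, "n_cs")
    if len(ps) < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    rows = []
    for t in ps.columns:
        ps_t = ps[t].to_numpy(dtype=float)
        cs_t = cs[t].to_numpy(dtype=float)
        tot = ps_t.sum() + cs_t.sum()
        if tot == 0:
            rows.append({"time_min": int(t), "statistic": np.nan, "null_lo": np.nan,
                         "null_hi": np.nan, "p_value": np.nan, "significant": False,
                         "skipped": True})
            continue
        obs_focal = ps_t if focal == "PS" else cs_t
        obs = float(obs_focal.sum() / tot)
        swap = rng.random(size=(n_iter, ps_t.size)) < 0.5
        perm_ps = np.where(swap, cs_t, ps_t)
        perm_focal = perm_ps if focal == "PS" else (ps_t + cs_t) - perm_ps
        null = perm_focal.sum(axis=1) / tot
        lo, hi = np.percentile(null, [2.5, 97.5])
        p = _two_sided_p(null, obs)
        rows.append(
            {"time_min": int(t), "statistic": obs, "null_lo": lo, "null_hi": hi,
             "p_value": p, "significant": bool(p < 0.05), "skipped": False}
        )
    return TestResult("ps_cs_permutation", pd.DataFrame(rows), n_iter, seed,
                      notes={"focal": focal})


def occupancy_difference_distribution(table: pd.DataFrame) -> pd.DataFrame:
    """Integer-binned histogram of pooled ``n_ps - n_cs`` per recorded time.

    One row per (time_min, diff) with the number of trials; suitable as the
    direct input of external bimodality tests.
    """
    pooled = _pooled(table)
    pooled["diff"] = pooled["n_ps"] - pooled["n_cs"]
    out = (
        pooled.groupby(["time_min", "diff"])
        .size()
        .rename("n_trials")
        .reset_index()
        .sort_values(["time_min", "diff"])
        .reset_index(drop=True)
    )
    return out
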