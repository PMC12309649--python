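"""Resampling null models for group-level representation bias.

Question: are the maps that fall below a representation threshold biased
toward particular orders, families, habitats, or Red List categories?

Procedure: let m be the number of maps below threshold in the full set of
N maps.  Draw S random samples of m maps, uniformly *without replacement*,
from the full set, and count members of each group g in every sample.  The
observed count O_g is compared with the null distribution through:

* a signed percent difference
  ``D_g = 100 * (mean_null_count - O_g) / N_g`` — negative when the group
  has MORE underrepresented maps than expected (worse represented than
  chance), positive when fewer (better represented);
* a binomial tail probability with p = m / N (exact tail sums; since
  sampling is without replacement this is an approximation to the
  hypergeometric, which is available as an option);
* a significance flag: true when the central 95% interval of the
  per-sample differences ``100 * (c_s - O_g) / N_g`` excludes 0.

Because samples are drawn from the full set, per-sample group counts sum
to m whenever the groups partition the maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import ParameterError

DEFAULT_SAMPLES = 1000
SMALL_SAMPLE_FLOOR = 10

RESULT_COLUMNS = [
    "group", "n_group", "observed", "null_mean", "null_p2_5", "null_p97_5",
    "percent_difference", "p_value", "significant", "small_sample",
    "n_samples", "threshold", "seed",
]


def draw_null_counts(labels, m: int, n_samples: int,
                     rng: np.random.Generator | int | None = None
                     ) -> tuple[list, np.ndarray]:
    """Null distribution of per-group counts over random m-subsets of all maps.

    ``labels`` is one group label per map (NaN/None = no group; such maps are
    drawn like any other but counted in no group).  Returns
    ``(group_values, counts)`` with ``counts`` of shape (n_samples, n_groups).
    """
    labels = pd.Series(list(labels))
    n_total = len(labels)
    if not (0 < m <= n_total):
        raise ParameterError(f"sample size m={m} outside (0, {n_total}]")
    if n_samples < 1:
        raise ParameterError("need at least one sample")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    codes, groups = pd.factorize(labels, use_na_sentinel=True)
    n_groups = len(groups)
    counts = np.zeros((n_samples, n_groups), dtype=np.int64)
    for s in range(n_samples):
        pick = rng.choice(n_total, size=m, replace=False)
        picked = codes[pick]
        picked = picked[picked >= 0]
        counts[s] = np.bincount(picked, minlength=n_groups)
    return list(groups), counts


def percent_difference(observed: float, null_mean: float, n_group: int) -> float:
    """Signed effect size: 100 * (expected - observed) / group size.

    Negative = the group contributes more below-threshold maps than chance
    (worse represented); positive = fewer (better represented).
    """
    if n_group <= 0:
        raise ParameterError("empty group has no percent difference")
    return 100.0 * (null_mean - observed) / n_group


def binomial_probability(observed: int, n_group: int, p: float,
                         alternative: str = "two-sided") -> float:
    """Tail probability of the observed below-threshold count under Binomial(N_g, p).

    ``p`` is the marginal chance of any map being below threshold (m / N).
    Exact tail sums; two-sided = min(1, 2 * min(lower tail, upper tail)).
    """
    if not (0 < p < 1):
        raise ParameterError(f"degenerate success probability p={p}")
    lower = stats.binom.cdf(observed, n_group, p)
    upper = stats.binom.sf(observed - 1, n_group, p)
    if alternative == "less":
        return float(lower)
    if alternative == "greater":
        return float(upper)
    if alternative == "two-sided":
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ParameterError(f"unknown alternative {alternative!r}")


def hypergeometric_probability(observed: int, n_group: int, m: int, n_total: int,
                               alternative: str = "two-sided") -> float:
    """Exact tail probability under sampling without replacement."""
    lower = stats.hypergeom.cdf(observed, n_total, n_group, m)
    upper = stats.hypergeom.sf(observed - 1, n_total, n_group, m)
    if alternative == "less":
        return float(lower)
    if alternative == "greater":
        return float(upper)
    return float(min(1.0, 2.0 * min(lower, upper)))


def significance(sample_counts: np.ndarray, observed: int, n_group: int) -> bool:
    """True when the central 95% interval of per-sample differences excludes 0.

    The differences are ``100 * (c_s - O_g) / N_g`` over the null samples; the
    interval is the 2.5th..97.5th percentile band (not the full range).
    """
    sample_counts = np.asarray(sample_counts)
    if sample_counts.size < 100:
        raise ParameterError("need at least 100 samples for the interval rule")
    diffs = 100.0 * (sample_counts - observed) / n_group
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return bool(lo > 0.0 or hi < 0.0)


def evaluate_groups(summaries: pd.DataFrame, group_col: str, threshold: float,
                    n_samples: int = DEFAULT_SAMPLES, seed: int | None = 0,
                    test: str = "binomial",
                    small_floor: int = SMALL_SAMPLE_FLOOR) -> pd.DataFrame:
    """Full bias analysis of one grouping variable at one threshold.

    ``summaries`` is the per-map table (``pct_in_union``, ``group_col``);
    maps with missing percents are excluded, maps with missing group labels
    participate in the draws but count in no group.  One independent RNG
    stream per call; the seed is logged in the output.  Groups smaller than
    ``small_floor`` are reported but flagged small-sample.
    """
    usable = summaries[~summaries["pct_in_union"].isna()]
    labels = usable[group_col]
    below = usable["pct_in_union"] < threshold
    m = int(below.sum())
    n_total = len(usable)
    if m == 0 or m == n_total:
        raise ParameterError(
            f"all-or-none below threshold (m={m} of {n_total}); no bias test possible")
    rng = np.random.default_rng(seed)
    groups, counts = draw_null_counts(labels, m, n_samples, rng)

    rows = []
    p_marginal = m / n_total
    for j, g in enumerate(groups):
        n_g = int((labels == g).sum())
        if n_g == 0:
            continue
        o_g = int(((labels == g) & below).sum())
        null = counts[:, j]
        if test == "binomial":
            pval = binomial_probability(o_g, n_g, p_marginal)
        elif test == "hypergeometric":
            pval = hypergeometric_probability(o_g, n_g, m, n_total)
        else:
            raise ParameterError(f"unknown test {test!r}")
        rows.append({
            "group": g,
            "n_group": n_g,
            "observed": o_g,
            "null_mean": float(null.mean()),
            "null_p2_5": float(np.percentile(null, 2.5)),
            "null_p97_5": float(np.percentile(null, 97.5)),
            "percent_difference": percent_difference(o_g, float(null.mean()), n_g),
            "p_value": pval,
            "significant": significance(null, o_g, n_g),
            "small_sample": n_g < small_floor,
            "n_samples": n_samples,
            "threshold": threshold,
            "seed": seed,
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


@dataclass
class CalibrationResult:
    """Outcome of a null calibration run (labels independent of class)."""
    n_groups: int
    significant_rate: float
    mean_percent_difference: float
    se_percent_difference: float


def calibration_experiment(n_maps: int = 2000, n_groups: int = 10, m: int = 600,
                           n_samples: int = 500, replicates: int = 60,
                           seed: int | None = 0) -> CalibrationResult:
    """Measure the false-positive rate of the significance rule under the null.

    A fixed set of m 'below-threshold' maps is chosen once; group labels are
    then assigned at random (independently of that set) ``replicates`` times,
    each labelling giving ``n_groups`` equal groups.  Under this null the
    significance flag should fire at ~5% of groups and percent differences
    should average 0.
    """
    rng = np.random.default_rng(seed)
    observed_set = np.zeros(n_maps, dtype=bool)
    observed_set[rng.choice(n_maps, size=m, replace=False)] = True
    # shared null draws: S x m sampled map indices
    ids = np.empty((n_samples, m), dtype=np.int64)
    for s in range(n_samples):
        ids[s] = rng.choice(n_maps, size=m, replace=False)

    flags, diffs = [], []
    base = np.repeat(np.arange(n_groups), int(np.ceil(n_maps / n_groups)))[:n_maps]
    for _ in range(replicates):
        labels = rng.permutation(base)
        lab_ids = labels[ids]                      # (S, m) group of each sampled map
        for g in range(n_groups):
            n_g = int((labels == g).sum())
            o_g = int(observed_set[labels == g].sum())
            null = (lab_ids == g).sum(axis=1)
            flags.append(significance(null, o_g, n_g))
            diffs.append(percent_difference(o_g, float(null.mean()), n_g))
    diffs = np.asarray(diffs)
    return CalibrationResult(
        n_groups=len(flags),
        significant_rate=float(np.mean(flags)),
        mean_percent_difference=float(diffs.mean()),
        se_percent_difference=float(diffs.std(ddof=1) / np.sqrt(len(diffs))),
    )
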