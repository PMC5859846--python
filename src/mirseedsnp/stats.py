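"""Inferential statistics: 2x2 chi-square enrichment, two-sample t-test on
overlap scores, and hypergeometric over-representation of miRNA sets.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .records import ContingencyTable2x2, MirnaSetAnnotation, TestResult


def chi_square_2x2(
    table: ContingencyTable2x2, continuity_correction: bool = False
) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 table, df = 1.

    The statistic is Σ(O−E)²/E with expected counts from the margins; with
    ``continuity_correction`` the Yates-corrected statistic
    Σ(|O−E|−0.5)²/E is used instead (never larger than the uncorrected
    one).  A zero marginal leaves an expected cell at 0 and the test
    undefined; Fisher's exact test is the appropriate fallback there.
    """
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if np.any(expected == 0):
        raise ValueError(
            "a marginal total is zero, expected counts contain 0; "
            "use Fisher's exact test instead"
        )
    dev = np.abs(obs - expected)
    if continuity_correction:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev ** 2 / expected))
    p = float(sps.chi2.sf(stat, df=1))
    method = "Pearson chi-square" + (" (Yates)" if continuity_correction else "")
    return TestResult(statistic=stat, df=1, p_value=max(p, np.nextafter(0, 1)),
                      method=method)


def students_t_test(
    x: list[float], y: list[float], welch: bool = False
) -> TestResult:
    """Two-sided two-sample t-test; pooled variance (Student) by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    # relative tolerance: constant samples can show a tiny nonzero variance
    # from catastrophic cancellation
    scale = max(float(np.abs(x).max()), float(np.abs(y).max()), 1.0)
    tol = (1e-12 * scale) ** 2
    if np.var(x, ddof=1) <= tol and np.var(y, ddof=1) <= tol:
        if np.allclose(x.mean(), y.mean()):
            # identical constants: no evidence of any difference
            return TestResult(statistic=0.0, df=len(x) + len(y) - 2,
                              p_value=1.0, method="Student t-test (degenerate)")
        raise ValueError("both samples have (numerically) zero variance; "
                         "t-test undefined")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = int(res.df) if welch else len(x) + len(y) - 2
    return TestResult(
        statistic=float(res.statistic), df=df,
        p_value=max(float(res.pvalue), np.nextafter(0, 1)),
        method="Welch t-test" if welch else "Student t-test",
    )


def set_over_representation(
    query_mirnas: set[str],
    annotation: list[MirnaSetAnnotation],
    universe: set[str],
) -> list[dict]:
    """One-sided hypergeometric over-representation of the query in each set.

    Each annotation's member list is intersected with the universe before
    testing; p-values are Benjamini-Hochberg adjusted across sets and
    results are sorted by raw p.  P(X >= k) with N = |universe|,
    K = |set ∩ universe|, n = |query|, k = |query ∩ set|.
    """
    if not query_mirnas or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query_mirnas <= universe:
        raise ValueError("query must be a subset of the universe")
    n_universe, n_query = len(universe), len(query_mirnas)
    rows = []
    for ann in annotation:
        members = ann.member_mirna_names & universe
        k = len(query_mirnas & members)
        # survival function at k-1 gives P(X >= k)
        p = float(sps.hypergeom.sf(k - 1, n_universe, len(members), n_query))
        rows.append({
            "set_name": ann.set_name, "set_size": len(members), "overlap": k,
            "p_value": min(max(p, np.nextafter(0, 1)), 1.0),
        })
    if rows:
        adj = multipletests([r["p_value"] for r in rows], method="fdr_bh")[1]
        for r, q in zip(rows, adj):
            r["p_value_adjusted"] = float(q)
    rows.sort(key=lambda r: (r["p_value"], r["set_name"]))
    return rows
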