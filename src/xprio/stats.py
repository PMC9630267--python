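"""Statistical toolkit: Fisher enrichment, decile enrichment, burden tests,
and the one-tailed binomial protein-domain test.

Conventions (all reported in serialized results):

* Two-sided Fisher p is the sum of probabilities of all fixed-margin tables
  with probability <= the observed table's (the standard exact convention).
* The reported odds ratio is the unconditional sample OR ``(a*d)/(b*c)``;
  when any cell is zero, ``1e-4`` is added to every cell before forming the
  OR used for the log2 transform, keeping it finite.  The conditional MLE is
  exposed separately.
* Multiple testing uses Bonferroni with an explicit ``n_tests`` argument —
  the caller owns the test-family definition.
* Decile boundaries are the 10%..90% quantiles with linear interpolation
  between order statistics; genes are binned into right-closed intervals, so
  a value equal to a boundary falls in the lower decile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FisherResult",
    "DecileEnrichmentResult",
    "BurdenResult",
    "fisher_enrichment",
    "decile_enrichment",
    "burden_comparison",
    "binomial_domain_test",
]

_LOG_ADDEND = 1e-4


@dataclass
class FisherResult:
    """Two-sided Fisher exact test on a 2x2 table with Bonferroni adjustment."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    log2_odds_ratio: float
    p_value: float
    p_adjusted: float
    n_tests: int
    conditional_odds_ratio: float = float("nan")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["convention"] = "two_sided_exact;sample_or;log2_addend_1e-4;bonferroni"
        return d


def fisher_enrichment(table, n_tests: int = 1) -> FisherResult:
    """Two-sided Fisher exact test with the sample-OR/log2 pseudo-count rule.

    Parameters
    ----------
    table
        2x2 array-like of non-negative integer counts ``[[a, b], [c, d]]``.
    n_tests
        Bonferroni family size; ``p_adjusted = min(1, p * n_tests)``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("table total must be positive")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    (a, b), (c, d) = t

    cond_or, p = sps.fisher_exact(t, alternative="two-sided")
    with np.errstate(divide="ignore", invalid="ignore"):
        sample_or = (a * d) / (b * c) if b * c > 0 else (np.inf if a * d > 0 else np.nan)
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = (x + _LOG_ADDEND for x in (a, b, c, d))
        log2_or = float(np.log2((aa * dd) / (bb * cc)))
    else:
        log2_or = float(np.log2(sample_or))
    return FisherResult(
        table=((int(a), int(b)), (int(c), int(d))),
        odds_ratio=float(sample_or),
        log2_odds_ratio=log2_or,
        p_value=float(p),
        p_adjusted=float(min(1.0, p * n_tests)),
        n_tests=int(n_tests),
        conditional_odds_ratio=float(cond_or),
    )


@dataclass
class DecileEnrichmentResult:
    """Enrichment of the target class inside one decile of a metric."""

    decile: int                      # 1..10
    lower: float                     # value boundaries, (lower, upper]
    upper: float
    fisher: FisherResult = field(repr=False)
    enriched: bool = False
    depleted: bool = False

    def to_dict(self) -> dict:
        return {
            "decile": self.decile,
            "lower": self.lower,
            "upper": self.upper,
            "fisher": self.fisher.to_dict(),
            "enriched": self.enriched,
            "depleted": self.depleted,
        }


def decile_boundaries(values: np.ndarray) -> np.ndarray:
    """10%, 20%, ..., 90% quantiles (linear interpolation)."""
    return np.quantile(values, np.arange(1, 10) / 10, method="linear")


def assign_deciles(values: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Map values to deciles 1..10 using right-closed intervals.

    A value exactly equal to a boundary goes to the lower decile.
    """
    # count of boundaries strictly below the value -> 0..9
    return np.searchsorted(boundaries, values, side="left") + 1


def decile_enrichment(values, labels, n_tests: int = 10, alpha: float = 0.05):
    """Per-decile Fisher enrichment of ``confirmed`` genes over a metric.

    Parameters
    ----------
    values
        Mapping/Series gene -> metric value; NaNs are dropped (genes without
        the metric do not enter the pooled distribution).
    labels
        Mapping/Series gene -> label; genes labelled ``"confirmed"`` form the
        target class, everything else is "rest".
    n_tests
        Bonferroni family size for the adjusted p-values.
    alpha
        Significance level on the adjusted p for the enriched/depleted flags.

    Returns
    -------
    list of 10 :class:`DecileEnrichmentResult`, one per decile; deciles
    partition all non-missing genes.
    """
    v = pd.Series(values, dtype=float)
    lab = pd.Series(labels).reindex(v.index)
    keep = v.notna()
    v, lab = v[keep], lab[keep]
    if len(v) < 10:
        raise ValueError(f"need >= 10 non-missing values, got {len(v)}")
    bounds = decile_boundaries(v.to_numpy())
    dec = assign_deciles(v.to_numpy(), bounds)
    confirmed = (lab == "confirmed").to_numpy()
    n_conf, n_all = int(confirmed.sum()), len(v)

    edges = np.concatenate([[v.min()], bounds, [v.max()]])
    out = []
    for i in range(1, 11):
        in_dec = dec == i
        a = int((in_dec & confirmed).sum())          # confirmed, in decile
        b = n_conf - a                               # confirmed, outside
        c = int(in_dec.sum()) - a                    # rest, in decile
        d = (n_all - n_conf) - c                     # rest, outside
        fr = fisher_enrichment([[a, b], [c, d]], n_tests=n_tests)
        sig = fr.p_adjusted < alpha
        out.append(DecileEnrichmentResult(
            decile=i,
            lower=float(edges[i - 1]),
            upper=float(edges[i]),
            fisher=fr,
            enriched=bool(sig and fr.odds_ratio > 1),
            depleted=bool(sig and fr.odds_ratio < 1),
        ))
    return out


@dataclass
class BurdenResult:
    """Two-group variant-burden comparison (raw and CDS-length-normalized)."""

    u_raw: float
    p_raw: float
    p_raw_adjusted: float
    u_norm: float
    p_norm: float
    p_norm_adjusted: float
    pearson_r: float
    pearson_p: float
    n_a: int
    n_b: int


def _mannwhitney(x, y):
    """Two-sided Mann-Whitney U; exact for small tie-free samples, else
    normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    small = len(x) <= 50 and len(y) <= 50
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def burden_comparison(counts_a, counts_b, cds_lengths) -> BurdenResult:
    """Compare per-gene variant counts between two gene groups.

    Runs two-sided Mann-Whitney U tests on (i) raw counts and (ii) counts per
    kb of coding sequence, Bonferroni-adjusted over the two tests, and the
    Pearson correlation between CDS length and count over all genes pooled.

    ``counts_a``/``counts_b`` are Series indexed by gene; ``cds_lengths``
    (bases) must cover every gene in both groups.
    """
    ca = pd.Series(counts_a, dtype=float)
    cb = pd.Series(counts_b, dtype=float)
    if ca.empty or cb.empty:
        raise ValueError("both groups must be non-empty")
    L = pd.Series(cds_lengths, dtype=float)
    missing = [g for g in list(ca.index) + list(cb.index) if g not in L.index]
    if missing:
        raise ValueError(f"missing CDS lengths for genes: {missing[:5]}")
    per_kb_a = ca / (L.loc[ca.index] / 1000.0)
    per_kb_b = cb / (L.loc[cb.index] / 1000.0)

    u_raw, p_raw = _mannwhitney(ca, cb)
    u_norm, p_norm = _mannwhitney(per_kb_a, per_kb_b)

    pooled = pd.concat([ca, cb])
    r, rp = sps.pearsonr(L.loc[pooled.index], pooled)
    return BurdenResult(
        u_raw=u_raw, p_raw=p_raw, p_raw_adjusted=min(1.0, 2 * p_raw),
        u_norm=u_norm, p_norm=p_norm, p_norm_adjusted=min(1.0, 2 * p_norm),
        pearson_r=float(r), pearson_p=float(rp),
        n_a=len(ca), n_b=len(cb),
    )


def binomial_domain_test(k_in_domain: int, n_variants: int,
                         domain_aa: int, total_aa: int) -> float:
    """Upper-tail exact binomial test for variants clustering in domains.

    Computes ``P(X >= k)`` for ``X ~ Binomial(n, domain_aa / total_aa)`` —
    the probability of at least ``k_in_domain`` of ``n_variants`` falling in
    protein domains if variants land uniformly on the protein.
    """
    if not (0 <= k_in_domain <= n_variants):
        raise ValueError("require 0 <= k_in_domain <= n_variants")
    if not (0 < domain_aa <= total_aa):
        raise ValueError("require 0 < domain_aa <= total_aa")
    p = domain_aa / total_aa
    return float(sps.binom.sf(k_in_domain - 1, n_variants, p))
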