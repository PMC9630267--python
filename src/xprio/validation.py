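"""Post-prediction evidence aggregation.

Given a predicted gene set, compares variant burden between predicted and
non-predicted genes, tests database-overlap enrichment, and runs the
one-tailed binomial test for missense variants clustering in protein
domains.  Variant sources are opaque labels — inputs are pre-exported
TSVs, not licensed database dumps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as _stats

__all__ = ["VariantRecord", "damaging_filter", "burden_report",
           "overlap_report", "domain_report"]

VARIANT_TYPES = ("LoF", "missense", "splicing", "other")

#: scaled deleteriousness cutoff for damaging missense variants
DAMAGING_SCORE_MIN = 25.0


@dataclass
class VariantRecord:
    gene: str
    type: str
    source: str
    score: float | None = None          # scaled PHRED-like deleteriousness
    protein_position: int | None = None
    in_domain: bool | None = None

    def __post_init__(self):
        if self.type not in VARIANT_TYPES:
            raise ValueError(f"unknown variant type {self.type!r}")
        if self.protein_position is not None and self.protein_position < 1:
            raise ValueError("protein position must be >= 1")
        if self.in_domain is not None and self.protein_position is None:
            raise ValueError("in_domain requires a protein position")


def damaging_filter(variants: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Keep damaging variants: LoF unconditionally, missense with score >= 25.

    Missense variants without a score are excluded and counted in a
    ``no_score`` bucket.  Idempotent.  Returns (subset, report) where the
    report carries kept/dropped tallies and per-gene kept counts.
    """
    v = variants.copy()
    is_lof = v["type"] == "LoF"
    score = pd.to_numeric(v.get("score"), errors="coerce")
    is_damaging_mis = (v["type"] == "missense") & (score >= DAMAGING_SCORE_MIN)
    no_score_mis = (v["type"] == "missense") & score.isna()
    kept = v[is_lof | is_damaging_mis]
    report = {
        "n_input": int(len(v)),
        "n_kept": int(len(kept)),
        "n_no_score_missense": int(no_score_mis.sum()),
        "n_dropped_other": int(len(v) - len(kept)),
        "per_gene": kept.groupby("gene").size().to_dict(),
    }
    return kept, report


def burden_report(counts: pd.Series, predicted: pd.Series,
                  cds_lengths: pd.Series) -> dict:
    """Variant-burden comparison between predicted and non-predicted genes.

    Delegates the raw and CDS-normalized Mann-Whitney tests and the CDS
    length/count Pearson correlation to :func:`xprio.stats.burden_comparison`,
    and adds a Fisher test of "has >= 1 reported variant" versus prediction
    status.
    """
    predicted = predicted.astype(bool)
    counts = counts.reindex(predicted.index).fillna(0)
    a = counts[predicted]
    b = counts[~predicted]
    res = _stats.burden_comparison(a, b, cds_lengths)
    has_var = counts > 0
    fisher = _stats.fisher_enrichment(
        [[int((has_var & predicted).sum()), int((~has_var & predicted).sum())],
         [int((has_var & ~predicted).sum()), int((~has_var & ~predicted).sum())]])
    return {"burden": res.__dict__, "has_variant_fisher": fisher.to_dict()}


def overlap_report(predicted: pd.Series,
                   memberships: dict[str, set[str]]) -> dict:
    """Database-overlap enrichment of predicted genes.

    ``memberships`` maps gene -> set of database names.  Emits both readings
    of the overlap question: a Fisher test on membership in at least one
    database, and a Mann-Whitney test on the number of databases per gene,
    plus per-database counts.  An empty map skips the tests with a notice.
    """
    predicted = predicted.astype(bool)
    n_dbs = pd.Series({g: len(memberships.get(g, ())) for g in predicted.index})
    if n_dbs.sum() == 0:
        return {"skipped": "empty database membership map"}
    member = n_dbs > 0
    fisher = _stats.fisher_enrichment(
        [[int((member & predicted).sum()), int((~member & predicted).sum())],
         [int((member & ~predicted).sum()), int((~member & ~predicted).sum())]])
    u, p = _stats._mannwhitney(n_dbs[predicted], n_dbs[~predicted])
    per_db: dict[str, int] = {}
    for dbs in memberships.values():
        for db in dbs:
            per_db[db] = per_db.get(db, 0) + 1
    return {
        "membership_fisher": fisher.to_dict(),
        "n_databases_mannwhitney": {"u": u, "p": p},
        "per_database_counts": per_db,
    }


def domain_report(variants: pd.DataFrame, domains: pd.DataFrame) -> dict:
    """Pooled binomial test for missense variants landing in protein domains.

    Pools missense variants across the gene set covered by ``domains``
    (columns gene, domain_aa, total_aa) and delegates to
    :func:`xprio.stats.binomial_domain_test` with k = in-domain missense
    count, n = missense count, and the summed domain/protein lengths.
    """
    if (domains["total_aa"] <= 0).any():
        raise ValueError("total_aa must be positive")
    genes = set(domains["gene"])
    mis = variants[(variants["type"] == "missense")
                   & variants["gene"].isin(genes)
                   & variants["in_domain"].notna()]
    n = int(len(mis))
    if n == 0:
        return {"skipped": "no missense variants with domain annotation"}
    k = int(mis["in_domain"].astype(bool).sum())
    domain_aa = int(domains["domain_aa"].sum())
    total_aa = int(domains["total_aa"].sum())
    p = _stats.binomial_domain_test(k, n, domain_aa, total_aa)
    return {"k_in_domain": k, "n_missense": n, "domain_aa": domain_aa,
            "total_aa": total_aa, "fraction_in_domain": k / n,
            "expected_fraction": domain_aa / total_aa, "p_one_tailed": p}
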