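"""Gene universe annotation: disorder classes, phenotype flags, canonical
transcripts, close paralogues, X-inactivation consensus and the 10-subgroup
pre-classification that defines the machine-learning training classes.

Subgroup labels cross disorder class {C, PMT, ND} with brain association
{b, nb} (not applicable to ND genes) and homozygous-LoF tolerance {i, t}:
Cbi, Cbt, Cnbi, Cnbt, PMTbi, PMTbt, PMTnbi, PMTnbt, NDi, NDt — ten labels.
``Cbi`` (confirmed brain-disorder, LoF-intolerant) are the positive training
class; ``NDt`` (no-disorder, tolerant of homozygous LoF — "dispensable")
the negative class.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GeneRecord", "TranscriptModel", "ParalogueHit",
    "load_phenotype_terms", "match_phenotype_terms",
    "select_canonical_transcript", "flag_close_paralogues",
    "consensus_xci", "preclassify", "annotate_genes",
    "PHENOTYPE_FLAGS", "SUBGROUP_LABELS",
]

DISORDER_CLASSES = ("confirmed", "PMT", "no_disorder")
PHENOTYPE_FLAGS = ("neurologic_any", "intellectual_disability", "seizures",
                   "language", "motor", "spasticity", "ataxia")
SUBGROUP_LABELS = ("Cbi", "Cbt", "Cnbi", "Cnbt",
                   "PMTbi", "PMTbt", "PMTnbi", "PMTnbt", "NDi", "NDt")
XCI_CALLS = ("escape", "non_escape", "variable")


class AnnotationError(ValueError):
    pass


@dataclass
class TranscriptModel:
    transcript_id: str
    gene: str
    mane_select: bool
    appris_annotated: bool
    length: int
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.length <= 0:
            raise AnnotationError(f"{self.transcript_id}: length must be > 0")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)


@dataclass
class GeneRecord:
    """One gene with identity, position and classification state."""

    symbol: str
    chromosome: str
    tss: int
    strand: str
    cds_intervals: list[tuple[int, int]]
    disorder_class: str
    par_flag: bool = False
    cs_available: bool = False
    phenotype_flags: dict[str, bool] = field(default_factory=dict)
    brain_flag: bool | None = None   # None = not applicable (no-disorder genes)
    lof_tolerant: bool = False

    def __post_init__(self):
        if self.disorder_class not in DISORDER_CLASSES:
            raise AnnotationError(
                f"{self.symbol}: unknown disorder_class {self.disorder_class!r}")
        prev = -1
        for s, e in self.cds_intervals:
            if e <= s:
                raise AnnotationError(f"{self.symbol}: empty CDS interval [{s},{e})")
            if s < prev:
                raise AnnotationError(f"{self.symbol}: CDS intervals overlap/unsorted")
            prev = e
        if not self.cs_available and any(self.phenotype_flags.values()):
            raise AnnotationError(
                f"{self.symbol}: phenotype flags set without clinical-synopsis data")
        if (self.brain_flag is None) != (self.disorder_class == "no_disorder"):
            raise AnnotationError(
                f"{self.symbol}: brain_flag must be not-applicable iff no_disorder")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)


@dataclass
class ParalogueHit:
    query: str
    target: str
    target_pct: float   # % of paralogue sequence matching the query
    query_pct: float    # % of query sequence matching the paralogue

    def __post_init__(self):
        for v in (self.target_pct, self.query_pct):
            if not 0 <= v <= 100:
                raise AnnotationError("identity percentages must be in [0, 100]")


def load_phenotype_terms(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load the phrase lists used for clinical-synopsis phenotype flagging."""
    if path is None:
        text = resources.files("xprio.data").joinpath("phenotype_terms.yaml").read_text()
    else:
        text = Path(path).read_text()
    terms = yaml.safe_load(text)
    for flag, phrases in terms.items():
        if not phrases:
            raise AnnotationError(f"empty term list for phenotype flag {flag!r}")
    return terms


def match_phenotype_terms(synopsis_text: str,
                          term_lists: dict[str, list[str]]) -> dict[str, bool]:
    """Flag clinical phenotypes by case-insensitive substring search.

    ``synopsis_text`` is the free-text neurologic section of a clinical
    synopsis. ``neurologic_any`` is true iff the section is non-empty; each
    other flag is true iff any of its phrases occurs as a substring.  There
    is no negation handling ("no seizures reported" sets the seizures flag).
    """
    for flag, phrases in term_lists.items():
        if not phrases:
            raise AnnotationError(f"empty term list for phenotype flag {flag!r}")
    text = (synopsis_text or "").lower()
    flags = {"neurologic_any": bool(text.strip())}
    for flag, phrases in term_lists.items():
        flags[flag] = any(p.lower() in text for p in phrases)
    return flags


def select_canonical_transcript(transcripts: list[TranscriptModel]) -> TranscriptModel:
    """Pick one canonical transcript per gene.

    Priority: (i) the MANE Select transcript; (ii) the longest
    APPRIS-annotated transcript; (iii) the only transcript if exactly one
    exists. Length ties break lexicographically on transcript id. A gene
    with multiple transcripts but neither annotation is an error.
    """
    if not transcripts:
        raise AnnotationError("empty transcript list")
    genes = {t.gene for t in transcripts}
    if len(genes) > 1:
        raise AnnotationError(f"transcripts from multiple genes: {sorted(genes)}")
    mane = [t for t in transcripts if t.mane_select]
    if mane:
        return min(mane, key=lambda t: (-t.length, t.transcript_id))
    appris = [t for t in transcripts if t.appris_annotated]
    if appris:
        return min(appris, key=lambda t: (-t.length, t.transcript_id))
    if len(transcripts) == 1:
        return transcripts[0]
    raise AnnotationError(
        f"gene {genes.pop()}: no MANE or APPRIS transcript among {len(transcripts)}")


def flag_close_paralogues(hits: list[ParalogueHit],
                          percentile: float = 95.0) -> dict[str, bool]:
    """Flag genes with at least one "close" paralogue.

    Thresholds are the given percentile (linear interpolation between order
    statistics) of the target-identity and query-identity distributions over
    *all* hits, computed separately; a gene is flagged iff some hit exceeds
    both thresholds strictly.
    """
    if not 0 < percentile < 100:
        raise AnnotationError("percentile must be in (0, 100)")
    if not hits:
        return {}
    t = np.percentile([h.target_pct for h in hits], percentile)
    q = np.percentile([h.query_pct for h in hits], percentile)
    flags: dict[str, bool] = {}
    for h in hits:
        close = h.target_pct > t and h.query_pct > q
        flags[h.query] = flags.get(h.query, False) or close
    return flags


def consensus_xci(calls: list[str], min_studies: int = 2) -> str:
    """Consensus X-inactivation category from per-study calls.

    Seven categories by agreement: ``high_conf_escape`` / ``high_conf_non_escape``
    when all or all-but-one studies agree; ``low_conf_*`` for a strict
    plurality; ``variable`` when "variable" is the strictly modal call;
    ``discordant`` when escape and non-escape counts are equal; and
    ``not_available`` with fewer than ``min_studies`` reports.  The exact
    vote margins are this package's convention — the source categories are
    qualitative.
    """
    unknown = set(calls) - set(XCI_CALLS)
    if unknown:
        raise AnnotationError(f"unknown XCI call labels: {sorted(unknown)}")
    n = len(calls)
    if n < min_studies:
        return "not_available"
    c = Counter(calls)
    e, ne, v = c["escape"], c["non_escape"], c["variable"]
    if v > e and v > ne:
        return "variable"
    if e == ne:
        return "discordant"
    winner, w = ("escape", e) if e > ne else ("non_escape", ne)
    conf = "high_conf" if w >= n - 1 else "low_conf"
    return f"{conf}_{winner}"


def preclassify(genes: list[GeneRecord]) -> dict[str, str]:
    """Assign each gene its 10-subgroup pre-classification label.

    Cross of disorder class x brain association x LoF tolerance; no-disorder
    genes carry no brain axis.  ``Cbi`` and ``NDt`` are the training classes.
    """
    out: dict[str, str] = {}
    for g in genes:
        tol = "t" if g.lof_tolerant else "i"
        if g.disorder_class == "no_disorder":
            if g.brain_flag is not None:
                raise AnnotationError(
                    f"{g.symbol}: brain_flag set on a no_disorder gene")
            out[g.symbol] = f"ND{tol}"
        else:
            prefix = "C" if g.disorder_class == "confirmed" else "PMT"
            brain = "b" if g.brain_flag else "nb"
            out[g.symbol] = f"{prefix}{brain}{tol}"
    return out


def annotate_genes(genes: pd.DataFrame,
                   term_lists: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Annotate a genes table: phenotype flags from synopsis text + subgroups.

    Expects columns ``symbol, chromosome, tss, strand, disorder_class,
    cs_available, brain_flag, lof_tolerant, par_flag`` and optionally
    ``clinical_synopsis``.  Returns a copy with one boolean column per
    phenotype flag and a ``subgroup`` column.
    """
    term_lists = term_lists if term_lists is not None else load_phenotype_terms()
    df = genes.copy()
    texts = df.get("clinical_synopsis", pd.Series("", index=df.index)).fillna("")
    cs = df["cs_available"].astype(bool)
    flag_rows = []
    for text, has_cs in zip(texts, cs):
        if has_cs:
            flag_rows.append(match_phenotype_terms(text, term_lists))
        else:
            flag_rows.append({f: False for f in PHENOTYPE_FLAGS})
    flags = pd.DataFrame(flag_rows, index=df.index).reindex(
        columns=list(PHENOTYPE_FLAGS), fill_value=False)
    df = pd.concat([df, flags], axis=1)

    subgroups = []
    for _, row in df.iterrows():
        brain = row["brain_flag"]
        brain = None if (pd.isna(brain) or row["disorder_class"] == "no_disorder") else bool(brain)
        rec = GeneRecord(
            symbol=row["symbol"], chromosome=str(row["chromosome"]),
            tss=int(row["tss"]), strand=row["strand"], cds_intervals=[],
            disorder_class=row["disorder_class"], par_flag=bool(row.get("par_flag", False)),
            cs_available=bool(row["cs_available"]),
            brain_flag=brain, lof_tolerant=bool(row["lof_tolerant"]),
        )
        subgroups.append(preclassify([rec])[rec.symbol])
    df["subgroup"] = subgroups
    return df
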