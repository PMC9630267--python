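"""Per-gene feature engineering: expression summaries and the tissue
specificity index tau, promoter CpG density, phastCons-style conservation
scores, positional features, and assembly of the 83-column feature table.

Coordinates are 0-based half-open throughout.  Missing values are recorded
in an explicit mask and never silently imputed at this stage — imputation
belongs to the ML preprocessing step, where it is fit on training genes
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema as _schema
from .annotation import TranscriptModel, select_canonical_transcript

__all__ = [
    "ConservationTrack", "FeatureTable", "FeatureInputs",
    "rpkm_to_tpm", "aggregate_brain", "compute_tau", "compute_cpg_density",
    "conservation_score", "positional_features", "assemble_feature_table",
    "PROMOTER_FLANK",
]

#: promoter window half-width: [TSS - 2000, TSS + 2000) on the gene strand
PROMOTER_FLANK = 2000


class FeatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# expression

def rpkm_to_tpm(rpkm: pd.DataFrame) -> pd.DataFrame:
    """Convert an RPKM gene x sample matrix to TPM.

    TPM_g = RPKM_g / sum_g RPKM_g * 1e6, per sample; each sample column of
    the result sums to one million.
    """
    if (rpkm.to_numpy() < 0).any():
        raise FeatureError("RPKM values must be non-negative")
    sums = rpkm.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise FeatureError(f"all-zero sample(s): {list(zero.index)[:5]}")
    return rpkm / sums * 1e6


def aggregate_brain(values: dict[str, float], cerebellar_tissues: set[str],
                    brain_tissues: set[str]) -> tuple[float, float]:
    """Collapse brain regions into (cerebellar, other-brain) metavalues.

    Each metavalue is the median TPM over the named tissues.  The two sets
    must be non-empty, disjoint, and present in ``values``.
    """
    cset, bset = set(cerebellar_tissues), set(brain_tissues)
    if not cset or not bset:
        raise FeatureError("tissue sets must be non-empty")
    if cset & bset:
        raise FeatureError(f"tissue sets overlap: {sorted(cset & bset)}")
    missing = (cset | bset) - set(values)
    if missing:
        raise FeatureError(f"tissues absent from values: {sorted(missing)}")
    cereb = float(np.median([values[t] for t in sorted(cset)]))
    brain = float(np.median([values[t] for t in sorted(bset)]))
    return cereb, brain


def compute_tau(aggregated: dict[str, float]) -> float | None:
    """Tissue specificity index tau on a brain-aggregated expression profile.

    Values are transformed to log2(TPM + 1); with x_i the transformed value
    divided by the maximum over the N tissues,

        tau = sum_i (1 - x_i) / (N - 1).

    tau is 0 for uniform expression and 1 for single-tissue expression.
    Returns ``None`` (missing) for an unexpressed gene (max = 0).
    """
    if len(aggregated) < 2:
        raise FeatureError(f"tau needs >= 2 tissues, got {len(aggregated)}")
    v = np.log2(np.asarray(list(aggregated.values()), dtype=float) + 1.0)
    if (v < 0).any():
        raise FeatureError("TPM values must be non-negative")
    m = v.max()
    if m == 0:
        return None
    x = v / m
    return float((1.0 - x).sum() / (len(x) - 1))


# ---------------------------------------------------------------------------
# sequence and track features

def compute_cpg_density(sequence: str) -> float | None:
    """Observed/expected CpG ratio of a promoter sequence.

    ratio = #CpG / (#C * #G) * N with N the sequence length; CpG
    dinucleotides are counted by a sliding one-base scan.  Returns ``None``
    when the sequence contains no C or no G (degenerate denominator).
    """
    if len(sequence) < 2:
        raise FeatureError("sequence must have length >= 2")
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise FeatureError("sequence alphabet must be {A,C,G,T,N}")
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        return None
    n_cpg = sum(1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G")
    return n_cpg / (n_c * n_g) * len(seq)


@dataclass
class ConservationTrack:
    """Piecewise-constant per-base conservation scores (bedGraph semantics).

    Per chromosome: sorted, non-overlapping half-open runs with a score in
    [0, 1] each.  Bases not covered by any run are treated as missing.
    """

    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConservationTrack":
        """Build from a bedGraph-like frame (chrom, start, end, score)."""
        runs = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            runs[str(chrom)] = (g["start"].to_numpy(np.int64),
                                g["end"].to_numpy(np.int64),
                                g["score"].to_numpy(float))
        return cls(runs)

    def to_frame(self) -> pd.DataFrame:
        parts = [pd.DataFrame({"chrom": c, "start": s, "end": e, "score": v})
                 for c, (s, e, v) in self.runs.items()]
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
            columns=["chrom", "start", "end", "score"])

    def scores_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Per-base scores at the given positions; NaN where uncovered."""
        out = np.full(len(positions), np.nan)
        if chrom not in self.runs:
            return out
        starts, ends, scores = self.runs[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        out[ok] = scores[idx[ok]]
        return out


def conservation_score(track: ConservationTrack, chrom: str,
                       intervals: list[tuple[int, int]]) -> float:
    """Mean per-base conservation over the union of half-open intervals.

    Bases missing from the track are excluded from numerator and
    denominator (missing track data is not evidence of non-conservation).
    Raises when no base is covered.
    """
    pos_parts = []
    for s, e in intervals:
        if e <= s:
            raise FeatureError(f"empty interval [{s},{e})")
        pos_parts.append(np.arange(s, e, dtype=np.int64))
    if not pos_parts:
        raise FeatureError("no intervals given")
    pos = np.unique(np.concatenate(pos_parts))   # union: bases counted once
    scores = track.scores_at(chrom, pos)
    covered = ~np.isnan(scores)
    if not covered.any():
        raise FeatureError(f"no track coverage on {chrom} for given intervals")
    return float(scores[covered].mean())


def positional_features(tss: int, centromere: tuple[int, int],
                        chromosome: tuple[int, int]) -> tuple[int, int]:
    """(distance to centromere, distance to the arm's telomere) for a TSS.

    The arm is decided by which side of the centromere the TSS falls on;
    a TSS inside the centromere interval is an annotation error.
    """
    cen_s, cen_e = centromere
    chrom_s, chrom_e = chromosome
    if cen_s <= tss < cen_e:
        raise FeatureError(f"TSS {tss} inside centromere [{cen_s},{cen_e})")
    if tss < cen_s:                       # p arm
        return cen_s - tss, tss - chrom_s
    return tss - cen_e, chrom_e - tss     # q arm


# ---------------------------------------------------------------------------
# table assembly

@dataclass
class FeatureTable:
    """Gene x 83-feature matrix with an explicit missingness mask.

    ``values`` holds NaN wherever ``mask`` is True (missing).
    """

    values: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self):
        names = _schema.feature_names()
        if list(self.values.columns) != names:
            raise FeatureError(
                f"feature table must have exactly the {len(names)} schema columns")
        if self.values.shape != self.mask.shape:
            raise FeatureError("values and mask shapes differ")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def to_tsv(self, path) -> None:
        df = pd.concat(
            [self.values, self.mask.add_suffix("__missing").astype(int)], axis=1)
        with open(path, "w") as fh:
            fh.write("# xprio feature table; coordinates 0-based half-open; "
                     "__missing columns: 1 = value missing\n")
            df.to_csv(fh, sep="\t", index_label="symbol")

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="symbol")
        names = _schema.feature_names()
        return cls(df[names], df[[f"{n}__missing" for n in names]]
                   .astype(bool).rename(columns=lambda c: c[:-len("__missing")]))


@dataclass
class FeatureInputs:
    """Everything :func:`assemble_feature_table` consumes."""

    genes: pd.DataFrame              # symbol, chromosome, tss, strand, ...
    transcripts: pd.DataFrame        # transcript_id, gene, mane_select, appris_annotated, length, cds blocks
    constraint: pd.DataFrame         # per-transcript gnomAD-style metrics
    promoters: dict[str, str]        # gene -> promoter sequence
    track: ConservationTrack
    expression: pd.DataFrame         # gene x sample
    samples: pd.DataFrame            # sample -> tissue, sex, age_group, unit
    paralogues: pd.DataFrame         # query, target, target_pct, query_pct
    chromosomes: pd.DataFrame        # chromosome -> length, cen_start, cen_end
    tissue_groups: dict[str, list[str]]   # cerebellar, brain, nerve


def _cds_intervals(row) -> list[tuple[int, int]]:
    sizes = [int(x) for x in str(row["block_sizes"]).split(",") if x != ""]
    starts = [int(x) for x in str(row["block_starts"]).split(",") if x != ""]
    return [(row["start"] + s, row["start"] + s + sz) for s, sz in zip(starts, sizes)]


class _ExpressionSummarizer:
    """Precomputed sample-column index sets for fast per-gene summaries."""

    def __init__(self, expr: pd.DataFrame, samples: pd.DataFrame,
                 groups: dict[str, list[str]]):
        sch = _schema.load_schema()
        self.names = sch["expression_adult"] + sch["expression_developmental"]
        self.expr = expr
        self.matrix = expr.to_numpy(float)
        self.gene_row = {g: i for i, g in enumerate(expr.index)}
        samples = samples.loc[[s for s in samples.index if s in expr.columns]]
        col = {s: j for j, s in enumerate(expr.columns)}

        adult = samples[samples["age_group"] == "adult"]
        self.cereb = set(groups["cerebellar"])
        self.brain = set(groups["brain"])
        nerve = groups["nerve"]
        self.nerve = set(nerve) if not isinstance(nerve, str) else {nerve}

        def idx(sel) -> np.ndarray:
            return np.array([col[s] for s in sel.index], dtype=int)

        self.cells: dict[str, np.ndarray] = {}
        for tag, tissues in (("Brain", self.brain), ("Cereb", self.cereb),
                             ("Nerve", self.nerve)):
            by_tissue = adult[adult["tissue"].isin(tissues)]
            for sex in ("F", "M"):
                self.cells[f"{tag}_{sex}"] = idx(by_tissue[by_tissue["sex"] == sex])
            if tag != "Nerve":
                self.cells[f"{tag}_all"] = idx(by_tissue)

        # per-(sex, tissue) column sets for the tau median profile
        self.tau_tissues: dict[str | None, list[tuple[str, np.ndarray]]] = {}
        for sex in (None, "F", "M"):
            sel = adult if sex is None else adult[adult["sex"] == sex]
            self.tau_tissues[sex] = [(t, idx(grp))
                                     for t, grp in sel.groupby("tissue")]

        dev = samples[samples["age_group"].isin(["Pre", "Post1", "Post2"])]
        for tag, ages in (("Pre", ["Pre"]), ("Post1", ["Post1"]),
                          ("Post2", ["Post2"]), ("Post", ["Post1", "Post2"])):
            sub = dev[dev["age_group"].isin(ages)]
            for sex in ("F", "M"):
                self.cells[f"dev_{tag}_{sex}"] = idx(sub[sub["sex"] == sex])

    def _tau(self, row: np.ndarray, sex: str | None) -> float | None:
        med = {t: float(np.median(row[cols]))
               for t, cols in self.tau_tissues[sex] if len(cols)}
        if len(med) < 2 or not (self.cereb | self.brain) <= set(med):
            return None
        c_meta, b_meta = aggregate_brain(med, self.cereb, self.brain)
        profile = {t: v for t, v in med.items()
                   if t not in self.cereb | self.brain}
        profile["__cerebellar__"], profile["__brain__"] = c_meta, b_meta
        return compute_tau(profile)

    def features_for(self, gene: str) -> dict[str, float | None]:
        out: dict[str, float | None] = {n: None for n in self.names}
        i = self.gene_row.get(gene)
        if i is None:
            return out
        row = self.matrix[i]

        def put(name: str, cols: np.ndarray):
            if len(cols) >= 2:
                vals = row[cols]
                out[f"mean_{name}"] = float(vals.mean())
                out[f"var_{name}"] = float(vals.var(ddof=1))

        for tag in ("Brain", "Cereb", "Nerve"):
            for sex in ("F", "M"):
                put(f"{tag}_{sex}", self.cells[f"{tag}_{sex}"])
            if tag != "Nerve":
                put(f"{tag}_all", self.cells[f"{tag}_all"])
        out["tau"] = self._tau(row, None)
        out["tau_1"] = self._tau(row, "F")
        out["tau_2"] = self._tau(row, "M")
        for tag in ("Pre", "Post1", "Post2", "Post"):
            for sex in ("F", "M"):
                cols = self.cells[f"dev_{tag}_{sex}"]
                if len(cols) >= 2:
                    vals = row[cols]
                    out[f"mean_{tag}_{sex}"] = float(vals.mean())
                    out[f"var_{tag}_{sex}"] = float(vals.var(ddof=1))
        return out


def assemble_feature_table(inputs: FeatureInputs) -> FeatureTable:
    """Assemble the 83-column feature table for every gene in the universe.

    Constraint metrics are taken per gene from the transcript with the
    lowest LOEUF.  Developmental expression samples in RPKM are converted to
    TPM before aggregation.  Missing values (no expression data, undefined
    tau or CpG ratio, uncovered conservation) go into the mask.
    """
    sch = _schema.load_schema()
    names = _schema.feature_names(sch)
    symbols = inputs.genes["symbol"]
    if symbols.duplicated().any():
        raise FeatureError(
            f"duplicate gene symbols: {symbols[symbols.duplicated()].tolist()[:5]}")

    # normalize developmental RPKM samples to TPM once
    expr = inputs.expression.copy()
    if "unit" in inputs.samples.columns:
        rpkm_cols = inputs.samples.index[inputs.samples["unit"] == "rpkm"]
        rpkm_cols = [c for c in rpkm_cols if c in expr.columns]
        if rpkm_cols:
            expr[rpkm_cols] = rpkm_to_tpm(expr[rpkm_cols])

    constraint_cols = sch["constraint"]
    cons = inputs.constraint.set_index("transcript_id")
    best_by_gene = {}
    for gene, grp in cons.groupby("gene"):
        best_by_gene[gene] = grp.loc[grp["loeuf"].idxmin()]

    chrom_meta = inputs.chromosomes.set_index("chromosome")
    tx_by_gene = {g: grp for g, grp in inputs.transcripts.groupby("gene")}
    para_by_gene = {g: grp for g, grp in inputs.paralogues.groupby("query")}
    close_thr = None
    if len(inputs.paralogues):
        close_thr = (np.percentile(inputs.paralogues["target_pct"], 95),
                     np.percentile(inputs.paralogues["query_pct"], 95))

    summarizer = _ExpressionSummarizer(expr, inputs.samples,
                                       inputs.tissue_groups)
    rows = []
    for _, g in inputs.genes.iterrows():
        sym, chrom, tss = g["symbol"], str(g["chromosome"]), int(g["tss"])
        feat: dict[str, float | None] = {}

        # constraint block — lowest-LOEUF transcript of the gene
        best = best_by_gene.get(sym)
        for c in constraint_cols:
            feat[c] = float(best[c]) if best is not None and pd.notna(best[c]) else None

        # canonical transcript & structure
        grp = tx_by_gene.get(sym)
        canonical = None
        if grp is not None and len(grp):
            models = [TranscriptModel(r["transcript_id"], sym, bool(r["mane_select"]),
                                      bool(r["appris_annotated"]), int(r["length"]),
                                      _cds_intervals(r))
                      for _, r in grp.iterrows()]
            canonical = select_canonical_transcript(models)
        if canonical is not None:
            feat["cds_length"] = float(canonical.cds_length)
            feat["exon_count"] = float(len(canonical.cds_intervals))
            feat["transcript_length"] = float(canonical.length)
        else:
            feat["cds_length"] = feat["exon_count"] = feat["transcript_length"] = None

        # promoter CpG density
        seq = inputs.promoters.get(sym)
        feat["promoter_cpg_density"] = compute_cpg_density(seq) if seq else None

        # conservation
        promoter_iv = [(max(0, tss - PROMOTER_FLANK), tss + PROMOTER_FLANK)]
        for name, ivs in (("exon_score", canonical.cds_intervals if canonical else []),
                          ("promoter_score", promoter_iv)):
            try:
                feat[name] = conservation_score(inputs.track, chrom, ivs) if ivs else None
            except FeatureError:
                feat[name] = None

        # position
        cm = chrom_meta.loc[chrom]
        d_cen, d_tel = positional_features(
            tss, (int(cm["cen_start"]), int(cm["cen_end"])), (0, int(cm["length"])))
        feat["dist_centromere"] = float(d_cen)
        feat["dist_telomere"] = float(d_tel)

        # paralogues
        hits = para_by_gene.get(sym)
        if hits is not None and len(hits):
            feat["n_paralogues"] = float(len(hits))
            feat["max_target_pct"] = float(hits["target_pct"].max())
            feat["max_query_pct"] = float(hits["query_pct"].max())
            feat["mean_target_pct"] = float(hits["target_pct"].mean())
            t_thr, q_thr = close_thr
            feat["n_close_paralogues"] = float(
                ((hits["target_pct"] > t_thr) & (hits["query_pct"] > q_thr)).sum())
        else:
            for c in sch["paralogue"]:
                feat[c] = 0.0

        feat.update(summarizer.features_for(sym))
        rows.append([feat[n] for n in names])

    values = pd.DataFrame(rows, index=pd.Index(symbols, name="symbol"),
                          columns=names, dtype=float)
    mask = values.isna()
    return FeatureTable(values=values, mask=mask)
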