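"""Synthetic gene universe with planted class structure.

Generates everything the downstream stages consume — gene annotations,
transcript models, promoter sequences, a conservation track, expression
matrices with sex/age/tissue strata, paralogue hits, variant tables,
protein-domain and database-membership tables — with known ground truth, so
the whole pipeline is testable without any download.

The generator's defaults encode the study conditions: class proportions
mirror the chromosome-X census (about 25% confirmed disorder genes, 3%
provisional/susceptibility/trait (PMT), 72% no-disorder), and the planted
feature shifts follow the observed direction of effects — disorder genes
get lower LOEUF, higher missense-Z, higher exonic conservation, broader and
brain-shifted expression, denser CpG promoters and fewer close paralogues.
Distribution families: normal for Z-scores, beta for bounded scores,
log-normal for expression-like and length-like quantities, Poisson for
counts.  Chromosome lengths are scaled-down constants, not real ones;
coordinates are 0-based half-open.

Two generation paths exist:

* :func:`generate_universe` — full raw-data universe (sequences, tracks,
  expression samples); features must then be *computed* by
  ``features.assemble_feature_table``.
* :func:`generate_feature_table` — direct draw of the 83-column feature
  table from the planted per-class distributions, for studies of the
  enrichment/ML stages where raw data adds nothing.

Truth labels are emitted separately (``truth.json``) so pipeline stages can
be run blind and scored afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema as _schema
from .features import ConservationTrack, FeatureInputs, FeatureTable

__all__ = [
    "SynthConfig", "FeatureEffect", "Universe",
    "default_feature_effects", "generate_universe",
    "generate_feature_table", "generate_promoter_sequence",
]

CLASSES = ("confirmed", "PMT", "no_disorder")

ADULT_TISSUES = {
    "cerebellar": ["Cerebellum", "CerebellarHemisphere"],
    "brain": ["Cortex", "FrontalCortex", "Hippocampus", "Amygdala",
              "Hypothalamus", "Striatum"],
    "nerve": "Nerve",
    "other": ["Liver", "Heart", "Lung", "Muscle", "Kidney", "Testis",
              "Skin", "WholeBlood", "Spleen"],
}

DATABASES = ["db_sysndd", "db_g2p", "db_panelapp", "db_radboud",
             "db_sfari", "db_dbd", "db_orphanet"]


class ConfigError(ValueError):
    """A SynthConfig field violates its contract."""


@dataclass
class FeatureEffect:
    """Planted per-class distribution of one feature.

    ``family`` is one of normal / beta / lognormal / poisson / uniform;
    ``params`` maps class -> (loc, scale).  Interpretation: normal =
    (mean, sd); beta = (mean, concentration), optionally scaled by
    ``mult``; lognormal = (mean of log2 values, sd of log2); poisson =
    (rate, ignored); uniform = (low, high).
    """

    family: str
    params: dict[str, tuple[float, float]]
    mult: float = 1.0

    def sample(self, rng: np.random.Generator, cls: np.ndarray) -> np.ndarray:
        out = np.empty(len(cls))
        for c in CLASSES:
            m = cls == c
            if not m.any():
                continue
            loc, scale = self.params[c]
            k = int(m.sum())
            if self.family == "normal":
                out[m] = rng.normal(loc, scale, k)
            elif self.family == "beta":
                a = max(loc, 1e-3) * scale
                b = max(1.0 - loc, 1e-3) * scale
                out[m] = rng.beta(a, b, k) * self.mult
            elif self.family == "lognormal":
                out[m] = np.exp2(rng.normal(loc, scale, k))
            elif self.family == "poisson":
                out[m] = rng.poisson(loc, k)
            elif self.family == "uniform":
                out[m] = rng.uniform(loc, scale, k)
            else:
                raise ConfigError(f"unknown distribution family {self.family!r}")
        return out


def _sym(conf, pmt, nd):
    return {"confirmed": conf, "PMT": pmt, "no_disorder": nd}


def default_feature_effects() -> dict[str, FeatureEffect]:
    """Planted distributions for all 83 features (editable per config).

    Only the directions and rough magnitudes matter; PMT sits between the
    confirmed and no-disorder classes throughout, mirroring the observed
    intermediate behaviour of provisional genes.
    """
    E = FeatureEffect
    fx: dict[str, FeatureEffect] = {
        # headline constraint metrics
        "loeuf": E("beta", _sym((0.13, 14), (0.25, 10), (0.45, 6)), mult=2.0),
        "mis_z": E("normal", _sym((2.5, 1.0), (1.2, 1.1), (0.0, 1.2))),
        "syn_z": E("normal", _sym((0.0, 1.0), (0.0, 1.0), (0.0, 1.0))),
        "lof_z": E("normal", _sym((4.0, 1.5), (2.0, 1.5), (0.5, 1.5))),
        "pli": E("beta", _sym((0.85, 3), (0.5, 2), (0.15, 2))),
        "pnull": E("beta", _sym((0.1, 3), (0.35, 2), (0.6, 2))),
        "prec": E("beta", _sym((0.4, 3), (0.45, 3), (0.35, 3))),
        "oe_mis_pphen": E("beta", _sym((0.35, 8), (0.55, 6), (0.8, 5)), mult=1.5),
        "max_af": E("beta", _sym((0.02, 4), (0.1, 3), (0.3, 2))),
        "classic_caf": E("beta", _sym((0.03, 4), (0.12, 3), (0.35, 2))),
        # conservation
        "exon_score": E("beta", _sym((0.93, 22), (0.85, 12), (0.62, 5))),
        "promoter_score": E("beta", _sym((0.55, 8), (0.45, 7), (0.3, 5))),
        # expression drivers (log2 TPM means / tau targets)
        "tau": E("beta", _sym((0.3, 9), (0.5, 8), (0.72, 7))),
        "tau_1": E("beta", _sym((0.3, 9), (0.5, 8), (0.72, 7))),
        "tau_2": E("beta", _sym((0.32, 9), (0.52, 8), (0.74, 7))),
        "mean_Brain_all": E("lognormal", _sym((4.0, 0.7), (2.8, 0.8), (1.2, 0.9))),
        "mean_Pre_M": E("lognormal", _sym((4.2, 0.7), (3.0, 0.8), (1.5, 0.9))),
        "mean_Post_M": E("lognormal", _sym((3.8, 0.7), (2.8, 0.8), (1.4, 0.9))),
        # structure
        "cds_length": E("lognormal", _sym((11.2, 0.8), (10.8, 0.8), (10.4, 0.8))),
        "exon_count": E("poisson", _sym((10, 0), (8, 0), (7, 0))),
        "transcript_length": E("lognormal", _sym((11.9, 0.7), (11.5, 0.7), (11.1, 0.7))),
        "promoter_cpg_density": E("beta", _sym((0.5, 9), (0.4, 8), (0.3, 7)), mult=2.0),
        # position: uniform over a scaled arm
        "dist_centromere": E("uniform", _sym((0, 9e5), (0, 9e5), (0, 9e5))),
        "dist_telomere": E("uniform", _sym((0, 9e5), (0, 9e5), (0, 9e5))),
        # paralogy: no-disorder genes carry more high-identity paralogues
        "n_paralogues": E("poisson", _sym((1.2, 0), (2.0, 0), (3.0, 0))),
        "n_close_paralogues": E("poisson", _sym((0.05, 0), (0.2, 0), (0.5, 0))),
        "max_target_pct": E("beta", _sym((0.45, 5), (0.55, 5), (0.7, 5)), mult=100.0),
        "max_query_pct": E("beta", _sym((0.45, 5), (0.55, 5), (0.7, 5)), mult=100.0),
        "mean_target_pct": E("beta", _sym((0.4, 6), (0.5, 6), (0.6, 6)), mult=100.0),
    }
    # remaining constraint columns: mildly class-informative observed/expected
    # style metrics (disorder genes deplete LoF and damaging missense)
    oe_like = {"oe_lof": (0.1, 0.3, 0.7), "oe_lof_lower": (0.05, 0.2, 0.5),
               "oe_mis": (0.6, 0.75, 0.95), "oe_mis_lower": (0.5, 0.65, 0.85),
               "oe_mis_upper": (0.7, 0.85, 1.05), "oe_syn": (1.0, 1.0, 1.0),
               "oe_syn_lower": (0.9, 0.9, 0.9), "oe_syn_upper": (1.1, 1.1, 1.1)}
    for name, (c, p, n) in oe_like.items():
        fx[name] = FeatureEffect("normal", _sym((c, 0.12), (p, 0.12), (n, 0.15)))
    count_like = {"obs_lof": (2, 8, 20), "exp_lof": (25, 22, 22),
                  "obs_mis": (180, 230, 280), "exp_mis": (300, 300, 290),
                  "obs_syn": (120, 120, 118), "exp_syn": (120, 120, 118),
                  "obs_mis_pphen": (60, 90, 130), "exp_mis_pphen": (140, 140, 135),
                  "obs_het_lof": (2, 7, 18), "obs_hom_lof": (0.02, 0.3, 1.2),
                  "no_lofs": (40, 35, 25), "possible_lof": (300, 280, 270),
                  "possible_mis": (2200, 2100, 2000), "possible_syn": (800, 780, 760)}
    for name, (c, p, n) in count_like.items():
        fx[name] = FeatureEffect("poisson", _sym((c, 0), (p, 0), (n, 0)))
    mu_like = {"mu_lof": (-6.2, -6.1, -6.0), "mu_mis": (-4.8, -4.8, -4.7),
               "mu_syn": (-5.2, -5.2, -5.1)}
    for name, (c, p, n) in mu_like.items():
        fx[name] = FeatureEffect("normal", _sym((c, 0.2), (p, 0.2), (n, 0.2)))
    # remaining expression columns: realized through the expression model in
    # the full universe; these distributions serve the direct-draw path
    for tag, sexes in (("Brain", ("F", "M", "all")), ("Cereb", ("F", "M", "all")),
                       ("Nerve", ("F", "M"))):
        for s in sexes:
            fx.setdefault(f"mean_{tag}_{s}",
                          FeatureEffect("lognormal", _sym((4.0, 0.7), (2.8, 0.8), (1.2, 0.9))))
            fx.setdefault(f"var_{tag}_{s}",
                          FeatureEffect("lognormal", _sym((3.0, 1.0), (2.5, 1.0), (1.5, 1.0))))
    for age in ("Pre", "Post1", "Post2", "Post"):
        for s in ("F", "M"):
            fx.setdefault(f"mean_{age}_{s}",
                          FeatureEffect("lognormal", _sym((4.2, 0.7), (3.0, 0.8), (1.5, 0.9))))
            fx.setdefault(f"var_{age}_{s}",
                          FeatureEffect("lognormal", _sym((3.2, 1.0), (2.6, 1.0), (1.6, 1.0))))
    return fx


@dataclass
class SynthConfig:
    """Generator configuration; defaults are the study conditions."""

    n_genes: int = 1000
    chromosome_weights: dict[str, float] = field(
        default_factory=lambda: {"1": 0.25, "2": 0.2, "7": 0.2, "11": 0.15, "X": 0.2})
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"confirmed": 0.247, "PMT": 0.031, "no_disorder": 0.722})
    brain_fraction: float = 0.75
    lof_tolerant_fraction_by_class: dict[str, float] = field(
        default_factory=lambda: {"confirmed": 0.05, "PMT": 0.2, "no_disorder": 0.35})
    feature_effects: dict[str, FeatureEffect] = field(default_factory=default_feature_effects)
    promoter_gc_by_class: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"confirmed": (0.55, 1.0), "PMT": (0.5, 0.8),
                                 "no_disorder": (0.45, 0.55)})
    variant_rate_by_class: dict[str, float] = field(
        default_factory=lambda: {"confirmed": 4.0, "PMT": 2.5, "no_disorder": 1.0})
    seed: int = 0
    chromosome_length: int = 2_000_000
    centromere: tuple[int, int] = (900_000, 1_100_000)
    cs_available_fraction: float = 0.9
    par_fraction: float = 0.02
    promoter_length: int = 4001

    def validate(self) -> None:
        for name in ("chromosome_weights", "class_proportions"):
            total = sum(getattr(self, name).values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {total!r})")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be a non-negative integer")
        if set(self.class_proportions) != set(CLASSES):
            raise ConfigError("class_proportions must cover exactly "
                              f"{CLASSES}")
        for c in CLASSES:
            if c not in self.lof_tolerant_fraction_by_class:
                raise ConfigError(f"lof_tolerant_fraction_by_class missing {c!r}")
            if c not in self.promoter_gc_by_class:
                raise ConfigError(f"promoter_gc_by_class missing {c!r}")
            if c not in self.variant_rate_by_class:
                raise ConfigError(f"variant_rate_by_class missing {c!r}")
        missing = set(_schema.feature_names()) - set(self.feature_effects)
        if missing:
            raise ConfigError(
                f"feature_effects missing entries for: {sorted(missing)[:8]} ...")


# ---------------------------------------------------------------------------
# promoter sequences

_BASES = np.array(list("ACGT"))


def _markov_sequences(n: int, length: int, gc: np.ndarray, cpg: np.ndarray,
                      rng: np.random.Generator) -> list[str]:
    """Batch first-order Markov promoter generation.

    Marginal base composition approximates (per-gene) GC content ``gc``;
    the C->G transition probability is scaled by ``cpg`` so the realized
    CpG observed/expected ratio approximates the requested enrichment,
    with G mass from non-C states raised to compensate the marginal.
    """
    if length < 2:
        raise ConfigError("promoter length must be >= 2")
    pC = gc / 2.0
    pG = gc / 2.0
    pA = (1.0 - gc) / 2.0
    # distribution after a C: G scaled by the enrichment ratio
    g_after_c = np.clip(cpg * pG, 0.0, 0.999)
    restC = 1.0 - g_after_c
    scaleC = restC / (1.0 - pG)
    distC = np.stack([pA * scaleC, pC * scaleC, g_after_c, pA * scaleC], axis=1)
    # distribution after a non-C: compensate so the G marginal stays ~pG
    g_after_n = np.clip(pG * (1.0 - pC * cpg) / (1.0 - pC), 0.0, 0.999)
    scaleN = (1.0 - g_after_n) / (1.0 - pG)
    distN = np.stack([pA * scaleN, pC * scaleN, g_after_n, pA * scaleN], axis=1)
    marginal = np.stack([pA, pC, pG, pA], axis=1)

    cumC, cumN, cumM = (np.cumsum(d, axis=1) for d in (distC, distN, marginal))
    seq = np.empty((n, length), dtype=np.int8)
    u = rng.random(n)
    seq[:, 0] = (u[:, None] > cumM).sum(axis=1)
    for j in range(1, length):
        prev_c = seq[:, j - 1] == 1
        cum = np.where(prev_c[:, None], cumC, cumN)
        u = rng.random(n)
        seq[:, j] = (u[:, None] > cum).sum(axis=1)
    return ["".join(row) for row in _BASES[seq]]


def generate_promoter_sequence(length: int, gc_fraction: float,
                               cpg_enrichment: float, seed: int) -> str:
    """One synthetic promoter sequence over {A,C,G,T}.

    Empirical GC approximates ``gc_fraction`` and the CpG observed/expected
    ratio approximates ``cpg_enrichment`` for sequences of a few kb;
    ``cpg_enrichment=0`` yields a sequence with no CG dinucleotide.
    """
    if length < 2:
        raise ConfigError("promoter length must be >= 2")
    if not 0 < gc_fraction < 1:
        raise ConfigError("gc_fraction must be in (0, 1)")
    if cpg_enrichment < 0:
        raise ConfigError("cpg_enrichment must be >= 0")
    rng = np.random.default_rng(seed)
    return _markov_sequences(1, length, np.array([gc_fraction]),
                             np.array([cpg_enrichment]), rng)[0]


# ---------------------------------------------------------------------------
# the universe

@dataclass
class Universe:
    """All generated inputs plus ground truth, as in-memory tables."""

    genes: pd.DataFrame
    transcripts: pd.DataFrame
    constraint: pd.DataFrame
    promoters: dict[str, str]
    track: ConservationTrack
    expression: pd.DataFrame
    samples: pd.DataFrame
    paralogues: pd.DataFrame
    variants: pd.DataFrame
    domains: pd.DataFrame
    db_membership: pd.DataFrame
    xci_calls: pd.DataFrame
    truth: dict
    chromosomes: pd.DataFrame

    def feature_inputs(self) -> FeatureInputs:
        return FeatureInputs(
            genes=self.genes, transcripts=self.transcripts,
            constraint=self.constraint, promoters=self.promoters,
            track=self.track, expression=self.expression, samples=self.samples,
            paralogues=self.paralogues, chromosomes=self.chromosomes,
            tissue_groups={"cerebellar": ADULT_TISSUES["cerebellar"],
                           "brain": ADULT_TISSUES["brain"],
                           "nerve": ADULT_TISSUES["nerve"]},
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all tables as plain-text files; returns name -> path."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def tsv(name, df, **kw):
            p = out / name
            df.to_csv(p, sep="\t", index=kw.pop("index", False), **kw)
            paths[name] = p

        tsv("genes.tsv", self.genes)
        tsv("constraint.tsv", self.constraint)
        tsv("expression.tsv", self.expression, index=True)
        tsv("samples.tsv", self.samples, index=True)
        tsv("paralogues.tsv", self.paralogues)
        tsv("variants.tsv", self.variants)
        tsv("domains.tsv", self.domains)
        tsv("db_membership.tsv", self.db_membership)
        tsv("xci_calls.tsv", self.xci_calls)
        tsv("chromosomes.tsv", self.chromosomes)

        p = out / "transcripts.bed"
        self.transcripts.to_csv(p, sep="\t", index=False)
        paths["transcripts.bed"] = p

        p = out / "promoters.fasta"
        with open(p, "w") as fh:
            for gene in self.genes["symbol"]:
                if gene in self.promoters:
                    fh.write(f">{gene}\n{self.promoters[gene]}\n")
        paths["promoters.fasta"] = p

        p = out / "conservation.bedGraph"
        self.track.to_frame().to_csv(p, sep="\t", index=False, header=False)
        paths["conservation.bedGraph"] = p

        p = out / "truth.json"
        with open(p, "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        paths["truth.json"] = p
        return paths


def _empty_universe(config: SynthConfig) -> Universe:
    gene_cols = ["symbol", "chromosome", "tss", "strand", "disorder_class",
                 "cs_available", "brain_flag", "lof_tolerant", "par_flag",
                 "clinical_synopsis"]
    chroms = pd.DataFrame({
        "chromosome": list(config.chromosome_weights),
        "length": config.chromosome_length,
        "cen_start": config.centromere[0], "cen_end": config.centromere[1]})
    return Universe(
        genes=pd.DataFrame(columns=gene_cols),
        transcripts=pd.DataFrame(columns=["chromosome", "start", "end", "transcript_id",
                                          "gene", "strand", "mane_select",
                                          "appris_annotated", "length",
                                          "block_sizes", "block_starts"]),
        constraint=pd.DataFrame(columns=["transcript_id", "gene"] + _schema.load_schema()["constraint"]),
        promoters={}, track=ConservationTrack(),
        expression=pd.DataFrame(), samples=_sample_sheet(),
        paralogues=pd.DataFrame(columns=["query", "target", "target_pct", "query_pct"]),
        variants=pd.DataFrame(columns=["gene", "type", "source", "score",
                                       "protein_position", "in_domain"]),
        domains=pd.DataFrame(columns=["gene", "domain_aa", "total_aa"]),
        db_membership=pd.DataFrame(columns=["gene", "databases"]),
        xci_calls=pd.DataFrame(columns=["gene", "study", "call"]),
        truth={"classes": {}, "config_seed": config.seed},
        chromosomes=chroms,
    )


def _sample_sheet() -> pd.DataFrame:
    """Fixed sample design: 2 adult samples per (tissue, sex) in TPM plus 3
    developmental samples per (age group, sex) in RPKM."""
    rows = []
    tissues = (ADULT_TISSUES["cerebellar"] + ADULT_TISSUES["brain"]
               + [ADULT_TISSUES["nerve"]] + ADULT_TISSUES["other"])
    for t in tissues:
        for sex in ("F", "M"):
            for i in (1, 2):
                rows.append((f"GTX_{t}_{sex}{i}", t, sex, "adult", "tpm"))
    for age in ("Pre", "Post1", "Post2"):
        for sex in ("F", "M"):
            for i in (1, 2, 3):
                rows.append((f"BSP_{age}_{sex}{i}", "brain_dev", sex, age, "rpkm"))
    df = pd.DataFrame(rows, columns=["sample", "tissue", "sex", "age_group", "unit"])
    return df.set_index("sample")


def _class_param(fx: dict[str, FeatureEffect], name: str, idx: int,
                 cls: np.ndarray) -> np.ndarray:
    """Per-gene parameter vector pulled from a feature-effect entry."""
    return np.array([fx[name].params[c][idx] for c in cls])


def generate_universe(config: SynthConfig) -> Universe:
    """Generate the full synthetic universe; identical seeds give identical
    output (byte-identical once written)."""
    config.validate()
    if config.n_genes == 0:
        return _empty_universe(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    fx = config.feature_effects

    # --- identities and classes -------------------------------------------
    symbols = np.array([f"G{i:05d}" for i in range(n)])
    chrom_names = list(config.chromosome_weights)
    chrom = rng.choice(chrom_names, size=n, p=list(config.chromosome_weights.values()))
    cls = rng.choice(CLASSES, size=n, p=[config.class_proportions[c] for c in CLASSES])
    has_disorder = cls != "no_disorder"
    brain = np.where(has_disorder, rng.random(n) < config.brain_fraction, False)
    tol_p = np.array([config.lof_tolerant_fraction_by_class[c] for c in cls])
    lof_tol = rng.random(n) < tol_p
    par = (chrom == "X") & (rng.random(n) < config.par_fraction)
    cs_avail = has_disorder & (rng.random(n) < config.cs_available_fraction)

    # --- gene placement ----------------------------------------------------
    cen_s, cen_e = config.centromere
    L = config.chromosome_length
    arm_q = rng.random(n) < (L - cen_e) / (L - (cen_e - cen_s))
    tss = np.where(
        arm_q,
        rng.integers(cen_e + 1000, L - 120_000, n),
        rng.integers(3000, cen_s - 120_000, n),
    )
    strand = rng.choice(["+", "-"], n)

    # --- transcript structure ---------------------------------------------
    cds_len = np.clip(fx["cds_length"].sample(rng, cls), 300, 60_000).astype(int)
    cds_len -= cds_len % 3
    exon_n = np.clip(fx["exon_count"].sample(rng, cls), 1, 40).astype(int)
    tx_len_target = np.clip(fx["transcript_length"].sample(rng, cls), 1, None)
    tx_len = np.maximum(cds_len + 200, tx_len_target).astype(int)

    tx_rows, cons_rows = [], []
    cons_cols = _schema.load_schema()["constraint"]
    gene_constraint = {c: fx[c].sample(rng, cls) for c in cons_cols}
    gene_constraint["loeuf"] = np.clip(gene_constraint["loeuf"], 1e-4, 2.0)

    for i in range(n):
        k = exon_n[i]
        cuts = np.sort(rng.choice(np.arange(1, cds_len[i] // 3), size=k - 1,
                                  replace=False)) * 3 if k > 1 else np.array([], int)
        sizes = np.diff(np.concatenate([[0], cuts, [cds_len[i]]]))
        introns = rng.integers(80, 2000, k - 1) if k > 1 else np.array([], int)
        starts = np.concatenate([[0], np.cumsum(sizes[:-1] + introns)])
        span = int(starts[-1] + sizes[-1])
        g_start = int(tss[i])
        tid = f"T{i:05d}.1"
        tx_rows.append((chrom[i], g_start, g_start + span, tid, symbols[i], strand[i],
                        rng.random() < 0.8, True, int(tx_len[i]),
                        ",".join(map(str, sizes)), ",".join(map(str, starts))))
        row = {"transcript_id": tid, "gene": symbols[i]}
        row.update({c: gene_constraint[c][i] for c in cons_cols})
        cons_rows.append(row)
        # secondary transcript for ~30% of genes: higher LOEUF, never MANE
        if rng.random() < 0.3:
            tid2 = f"T{i:05d}.2"
            tx_rows.append((chrom[i], g_start, g_start + span, tid2, symbols[i],
                            strand[i], False, True, max(200, int(tx_len[i] * 0.7)),
                            ",".join(map(str, sizes)), ",".join(map(str, starts))))
            row2 = dict(row, transcript_id=tid2)
            row2["loeuf"] = min(2.0, row["loeuf"] + abs(rng.normal(0.15, 0.05)))
            cons_rows.append(row2)

    transcripts = pd.DataFrame(tx_rows, columns=[
        "chromosome", "start", "end", "transcript_id", "gene", "strand",
        "mane_select", "appris_annotated", "length", "block_sizes", "block_starts"])
    constraint = pd.DataFrame(cons_rows)

    # --- promoters ---------------------------------------------------------
    gc = np.array([config.promoter_gc_by_class[c][0] for c in cls])
    cpg = np.array([config.promoter_gc_by_class[c][1] for c in cls])
    seqs = _markov_sequences(n, config.promoter_length, gc, cpg, rng)
    promoters = dict(zip(symbols, seqs))

    # --- conservation track ------------------------------------------------
    exon_target = np.clip(fx["exon_score"].sample(rng, cls), 1e-3, 1 - 1e-3)
    prom_target = np.clip(fx["promoter_score"].sample(rng, cls), 1e-3, 1 - 1e-3)
    run = 250
    t_chrom, t_start, t_end, t_score = [], [], [], []

    def add_runs(c, s, e, mean):
        conc = 30.0
        edges = list(range(s, e, run)) + [e]
        for a, b in zip(edges[:-1], edges[1:]):
            t_chrom.append(c)
            t_start.append(a)
            t_end.append(b)
            t_score.append(rng.beta(mean * conc, (1 - mean) * conc))

    canonical = transcripts[transcripts["transcript_id"].str.endswith(".1")]
    for i, (_, t) in enumerate(canonical.iterrows()):
        p0 = max(0, tss[i] - 2000)
        add_runs(chrom[i], p0, tss[i] + 2000, prom_target[i])
        sizes = [int(x) for x in t["block_sizes"].split(",")]
        starts = [int(x) for x in t["block_starts"].split(",")]
        for s0, sz in zip(starts, sizes):
            add_runs(chrom[i], t["start"] + s0, t["start"] + s0 + sz, exon_target[i])
    track_df = pd.DataFrame({"chrom": t_chrom, "start": t_start,
                             "end": t_end, "score": t_score})
    # drop overlapping runs (overlapping genes): keep first occurrence per start
    track_df = (track_df.sort_values(["chrom", "start"])
                .drop_duplicates(subset=["chrom", "start"], keep="first")
                .reset_index(drop=True))
    track = ConservationTrack.from_frame(track_df)

    # --- expression --------------------------------------------------------
    samples = _sample_sheet()
    brain_mu = _class_param(fx, "mean_Brain_all", 0, cls) + rng.normal(0, 0.3, n)
    tau_target = np.clip(fx["tau"].sample(rng, cls), 0.02, 0.98)
    breadth = np.clip(1.15 - tau_target, 0.05, 1.0)          # fraction of non-brain tissues expressed
    pre_mu = _class_param(fx, "mean_Pre_M", 0, cls) + rng.normal(0, 0.3, n)
    post_mu = _class_param(fx, "mean_Post_M", 0, cls) + rng.normal(0, 0.3, n)

    brain_set = set(ADULT_TISSUES["cerebellar"] + ADULT_TISSUES["brain"])
    nonbrain = [ADULT_TISSUES["nerve"]] + ADULT_TISSUES["other"]
    expr_cols = {}
    expressed = {t: rng.random(n) < breadth for t in nonbrain}
    other_mu = {t: np.where(expressed[t], brain_mu * rng.uniform(0.6, 1.1, n), -3.0)
                for t in nonbrain}
    for sample_id, meta in samples.iterrows():
        if meta["age_group"] == "adult":
            mu = brain_mu if meta["tissue"] in brain_set else other_mu[meta["tissue"]]
        elif meta["age_group"] == "Pre":
            mu = pre_mu
        else:
            mu = post_mu
        vals = np.exp2(mu + rng.normal(0, 0.4, n)) - 1.0
        expr_cols[sample_id] = np.clip(vals, 0.0, None)
    expression = pd.DataFrame(expr_cols, index=pd.Index(symbols, name="symbol"))

    # --- paralogues --------------------------------------------------------
    n_para = fx["n_paralogues"].sample(rng, cls).astype(int)
    pr_rows = []
    id_mean = np.clip(fx["max_target_pct"].sample(rng, cls) / 100.0, 0.05, 0.95)
    for i in range(n):
        for j in range(n_para[i]):
            m = id_mean[i]
            pr_rows.append((symbols[i], f"PARA_{i}_{j}",
                            100 * rng.beta(m * 8, (1 - m) * 8),
                            100 * rng.beta(m * 8, (1 - m) * 8)))
    paralogues = pd.DataFrame(pr_rows, columns=["query", "target",
                                                "target_pct", "query_pct"])

    # --- variants, domains, database membership ---------------------------
    rates = np.array([config.variant_rate_by_class[c] for c in cls])
    n_var = rng.poisson(rates * cds_len / 1000.0)
    total_aa = cds_len // 3
    domain_frac = np.clip(rng.beta(2, 5, n) + np.where(cls == "confirmed", 0.05, 0.0),
                          0.02, 0.9)
    var_rows = []
    vtypes = np.array(["missense", "LoF", "splicing", "other"])
    for i in range(n):
        for _ in range(n_var[i]):
            vt = vtypes[rng.choice(4, p=[0.6, 0.25, 0.1, 0.05])]
            score = float(np.clip(rng.normal(24, 6), 0, 60))
            if vt == "LoF" and rng.random() < 0.5:
                score = np.nan
            pos = int(rng.integers(1, total_aa[i] + 1))
            var_rows.append((symbols[i], vt,
                             rng.choice(["curated-DB-1", "curated-DB-2", "cohort"]),
                             score, pos, bool(rng.random() < domain_frac[i])))
    variants = pd.DataFrame(var_rows, columns=["gene", "type", "source", "score",
                                               "protein_position", "in_domain"])
    domains = pd.DataFrame({"gene": symbols,
                            "domain_aa": (domain_frac * total_aa).astype(int),
                            "total_aa": total_aa})
    db_p = np.where(cls == "confirmed", 0.25, np.where(cls == "PMT", 0.15, 0.04))
    member = rng.random((n, len(DATABASES))) < db_p[:, None]
    db_membership = pd.DataFrame({
        "gene": symbols,
        "databases": [";".join(np.array(DATABASES)[m]) for m in member]})

    # --- XCI calls (chrX genes only) --------------------------------------
    xci_rows = []
    for i in np.where(chrom == "X")[0]:
        n_studies = int(rng.integers(0, 8))
        p_escape = 0.9 if par[i] else 0.15
        for s in range(n_studies):
            r = rng.random()
            call = ("escape" if r < p_escape
                    else "variable" if r < p_escape + 0.1 else "non_escape")
            xci_rows.append((symbols[i], f"study{s + 1}", call))
    xci_calls = pd.DataFrame(xci_rows, columns=["gene", "study", "call"])

    # --- clinical synopsis text -------------------------------------------
    from .annotation import load_phenotype_terms
    terms = load_phenotype_terms()
    term_keys = list(terms)
    synopses = []
    for i in range(n):
        if not cs_avail[i]:
            synopses.append("")
        elif brain[i]:
            k = int(rng.integers(1, 4))
            picks = rng.choice(term_keys, size=k, replace=False)
            phrases = [terms[p][int(rng.integers(0, len(terms[p])))] for p in picks]
            synopses.append("; ".join(["Neurologic features"] + phrases))
        else:
            synopses.append("")   # non-brain disorder: empty neurologic section

    genes = pd.DataFrame({
        "symbol": symbols, "chromosome": chrom, "tss": tss, "strand": strand,
        "disorder_class": cls, "cs_available": cs_avail,
        "brain_flag": [bool(b) if d else None for b, d in zip(brain, has_disorder)],
        "lof_tolerant": lof_tol, "par_flag": par, "clinical_synopsis": synopses,
    })
    chromosomes = pd.DataFrame({
        "chromosome": chrom_names, "length": L,
        "cen_start": cen_s, "cen_end": cen_e})

    truth = {
        "config_seed": config.seed,
        "classes": {s: {"disorder_class": c, "brain": bool(b) if d else None,
                        "lof_tolerant": bool(t)}
                    for s, c, b, d, t in zip(symbols, cls, brain, has_disorder, lof_tol)},
        "feature_effects": {k: {"family": v.family, "mult": v.mult,
                                "params": v.params}
                            for k, v in fx.items()},
    }
    return Universe(genes=genes, transcripts=transcripts, constraint=constraint,
                    promoters=promoters, track=track, expression=expression,
                    samples=samples, paralogues=paralogues, variants=variants,
                    domains=domains, db_membership=db_membership,
                    xci_calls=xci_calls, truth=truth, chromosomes=chromosomes)


def generate_feature_table(config: SynthConfig):
    """Directly draw the 83-column feature table from the planted per-class
    distributions (no raw data).

    Returns ``(FeatureTable, labels)`` where ``labels`` carries
    disorder_class, brain_flag, lof_tolerant and the training subgroup.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    symbols = [f"G{i:05d}" for i in range(n)]
    cls = rng.choice(CLASSES, size=n,
                     p=[config.class_proportions[c] for c in CLASSES])
    has_disorder = cls != "no_disorder"
    brain = np.where(has_disorder, rng.random(n) < config.brain_fraction, False)
    tol_p = np.array([config.lof_tolerant_fraction_by_class[c] for c in cls])
    lof_tol = rng.random(n) < tol_p

    names = _schema.feature_names()
    cols = {}
    for name in names:
        v = config.feature_effects[name].sample(rng, cls)
        if name in _schema.UNIT_INTERVAL_FEATURES:
            v = np.clip(v, 0.0, 1.0)
        cols[name] = v
    values = pd.DataFrame(cols, index=pd.Index(symbols, name="symbol"))[names]
    table = FeatureTable(values=values, mask=values.isna())

    subgroup = []
    for c, b, t in zip(cls, brain, lof_tol):
        tol = "t" if t else "i"
        if c == "no_disorder":
            subgroup.append(f"ND{tol}")
        else:
            subgroup.append(f"{'C' if c == 'confirmed' else 'PMT'}{'b' if b else 'nb'}{tol}")
    labels = pd.DataFrame({
        "disorder_class": cls,
        "brain_flag": [bool(b) if d else None for b, d in zip(brain, has_disorder)],
        "lof_tolerant": lof_tol, "subgroup": subgroup,
    }, index=values.index)
    return table, labels
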