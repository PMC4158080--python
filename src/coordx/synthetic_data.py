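"""Synthetic cohort generator with planted regulatory structure.

Generates a fully labeled gene cohort — annotation, promoter/UTR/CDS
sequences, ribosome-profiling counts, Gro-seq counts and a tissue
expression matrix — whose statistical structure mirrors what is observed
in mammalian gene sets:

* promoter classes (canonical TATA / one-mismatch / TATA-less) at
  configurable frequencies (mouse default: 8.5% TATA overall);
* dependence between promoter class and uAUG presence (TATA genes carry
  uAUGs less often; defaults solved exactly from the mouse marginals:
  uAUG fraction 0.40 with TATA at 6.0% among uAUG vs 10.2% among
  uAUG-less genes);
* log-normal (right-skewed) region lengths whose medians depend on the
  (uAUG x TATA) group — uAUG and TATA-less genes are longer on every
  feature — with a shared per-gene "compactness" factor inducing positive
  correlation among the four lengths;
* latent (transcription rate, mRNA level, ribosomal density) triples tied
  together by a Gaussian copula calibrated to target Spearman
  correlations, plus group mean-shifts on the log scale (uAUG genes lower
  on all three; TATA genes higher, with the TATA advantage damped among
  uAUG genes);
* overdispersed negative-binomial sequencing counts around the latent
  means, and a log-normal tissue atlas whose breadth tracks mRNA level.

Everything is driven by one integer-seeded ``numpy`` generator, so a fixed
seed reproduces the cohort byte-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .genome_io import GeneModel, write_fasta, write_genepred
from .promoter_tata import MotifSpec, scan_promoter
from .utr_features import count_uaug

__all__ = [
    "SimConfig",
    "Cohort",
    "simulate_cohort",
    "plant_promoter",
    "plant_utr5",
    "sample_expression",
    "spearman_to_pearson",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
LATENTS = ("transcription", "mrna", "density")


def _default_length_medians() -> dict[str, dict[str, float]]:
    # medians in nt, keyed feature -> "<uaug>/<tata>" group; uAUG and
    # TATA-less genes are longer on every feature, uAUG-less gene span
    # about half the uAUG one, TATA contrasts damped within the uAUG class
    return {
        "utr5": {
            "uAUG_less/tata_less": 100.0,
            "uAUG_less/tata": 70.0,
            "uAUG/tata_less": 250.0,
            "uAUG/tata": 220.0,
        },
        "utr3": {
            "uAUG_less/tata_less": 450.0,
            "uAUG_less/tata": 300.0,
            "uAUG/tata_less": 800.0,
            "uAUG/tata": 700.0,
        },
        "cds": {
            "uAUG_less/tata_less": 1100.0,
            "uAUG_less/tata": 800.0,
            "uAUG/tata_less": 1600.0,
            "uAUG/tata": 1450.0,
        },
        "gene_length": {
            "uAUG_less/tata_less": 14000.0,
            "uAUG_less/tata": 8000.0,
            "uAUG/tata_less": 27000.0,
            "uAUG/tata": 23000.0,
        },
    }


def _default_copula() -> list[list[float]]:
    # target Spearman correlations among (transcription, mRNA, density)
    return [[1.0, 0.60, 0.25], [0.60, 1.0, 0.42], [0.25, 0.42, 1.0]]


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    Default calibration is the mouse-side one: TATA 8.5% of promoters
    (3.0% canonical + 5.5% one-mismatch), conditional uAUG probabilities
    solved exactly from the uAUG marginal 0.40 and the TATA frequencies
    6.0%/10.2% among uAUG/uAUG-less genes; 79-tissue atlas.  A human
    preset (TATA 5%, uAUG 47%, TATA 3.9%/5.7% by uAUG class) is available
    via :meth:`human`.
    """

    n_genes: int = 20000
    seed: int = 0
    # promoter classes and their coupling to uAUG presence
    p_canonical: float = 0.030
    p_one_mismatch: float = 0.055
    p_uaug_given_tata: float = 0.024 / 0.085
    p_uaug_given_tataless: float = 0.376 / 0.915
    # region lengths: log-normal, group medians below, one log-scale sigma,
    # and the variance share of the common per-gene compactness factor
    length_medians: dict[str, dict[str, float]] = field(default_factory=_default_length_medians)
    length_sigma: float = 1.0
    compactness_weight: float = 0.4
    # latent expression: Gaussian copula targets (Spearman) among
    # (transcription [reads/kb], mRNA [reads], ribosomal density), log-scale
    # sigmas and median scales, and additive log-scale group shifts
    copula_corr: list[list[float]] = field(default_factory=_default_copula)
    latent_sigma: dict[str, float] = field(
        default_factory=lambda: {"transcription": 1.2, "mrna": 1.2, "density": 0.8}
    )
    scale_transcription: float = 40.0  # median nascent rate, reads/kb
    scale_mrna: float = 300.0  # median mRNA reads per gene
    scale_te: float = 1.0  # median translation efficiency
    shift_uaug: dict[str, float] = field(
        default_factory=lambda: {"transcription": -0.45, "mrna": -0.55, "density": -0.35}
    )
    shift_tata: dict[str, float] = field(
        default_factory=lambda: {"transcription": 0.50, "mrna": 0.40, "density": 0.30}
    )
    tata_shift_damping_uaug: float = 0.3  # TATA advantage shrinks in uAUG genes
    # sequencing-count noise and pausing
    nb_dispersion: float = 100.0
    pausing_factor: float = 3.0  # first-kb read enrichment over the gene-body rate
    # tissue atlas
    n_tissues: int = 79
    tissue_scale: float = 500.0  # median per-gene tissue expression level
    tissue_sigma: float = 0.8  # across-tissue log-scale spread
    tissue_background: float = 20.0  # additive floor, expression units
    motif: str = "TATAWAG"
    max_mismatch: int = 1

    @classmethod
    def mouse(cls, **overrides) -> "SimConfig":
        return cls(**overrides)

    @classmethod
    def human(cls, **overrides) -> "SimConfig":
        base = dict(
            p_canonical=0.018,
            p_one_mismatch=0.032,
            p_uaug_given_tata=(0.039 * 0.47) / 0.05,
            p_uaug_given_tataless=(0.961 * 0.47) / 0.95,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def null(cls, **overrides) -> "SimConfig":
        """Calibration config: identical length medians and zero group
        shifts, so planted labels carry no expression or length signal.
        Used for copula-recovery and type-I-error checks."""
        flat = {g: 1000.0 for g in _default_length_medians()["utr5"]}
        base = dict(
            length_medians={f: dict(flat) for f in ("utr5", "utr3", "cds", "gene_length")},
            shift_uaug={k: 0.0 for k in LATENTS},
            shift_tata={k: 0.0 for k in LATENTS},
        )
        base["length_medians"]["gene_length"] = {g: 15000.0 for g in flat}
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        probs = (
            self.p_canonical,
            self.p_one_mismatch,
            self.p_uaug_given_tata,
            self.p_uaug_given_tataless,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.p_canonical + self.p_one_mismatch > 1.0:
            raise ValueError("p_canonical + p_one_mismatch exceeds 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for feat, groups in self.length_medians.items():
            for g, m in groups.items():
                if m <= 0:
                    raise ValueError(f"median length for {feat}[{g}] must be > 0, got {m}")
        C = np.asarray(self.copula_corr, dtype=float)
        if C.shape != (3, 3) or not np.allclose(C, C.T):
            raise ValueError("copula_corr must be a symmetric 3x3 matrix")
        if np.linalg.eigvalsh(spearman_to_pearson(C)).min() <= 0:
            raise ValueError("copula correlation matrix is not positive definite")
        if self.nb_dispersion <= 0 or self.length_sigma <= 0:
            raise ValueError("dispersion and sigma parameters must be positive")
        if not 0.0 <= self.compactness_weight <= 1.0:
            raise ValueError("compactness_weight must lie in [0, 1]")


def spearman_to_pearson(rho_s: np.ndarray) -> np.ndarray:
    """Latent Pearson correlation reproducing target Spearman under a
    Gaussian copula: r = 2 sin(pi * rho_s / 6)."""
    r = 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)
    np.fill_diagonal(r, 1.0)
    return r


def _random_seq(rng: np.random.Generator, length: int) -> str:
    if length <= 0:
        return ""
    return rng.choice(_BASES, size=length).tobytes().decode()


def plant_promoter(
    tata_class: str, rng: np.random.Generator, motif: MotifSpec | None = None, max_attempts: int = 1000
) -> str:
    """Draw a 26-nt promoter window guaranteed to scan as ``tata_class``.

    Canonical: an exact motif instance (IUPAC wildcards resolved uniformly)
    at a uniform offset in random flanks.  One-mismatch: an instance with
    exactly one planted violation, rejection-verified so no exact match
    arises in the flanks.  TATA-less: rejection-sampled until the minimum
    mismatch count over all offsets is >= 2.  Raises ``RuntimeError`` after
    ``max_attempts`` failed draws rather than emitting a wrong class.
    """
    from .genome_io import PROMOTER_WINDOW_LENGTH
    from .promoter_tata import IUPAC

    motif = motif or MotifSpec()
    L = PROMOTER_WINDOW_LENGTH
    k = len(motif.pattern)
    for _ in range(max_attempts):
        window = list(_random_seq(rng, L))
        if tata_class in ("canonical", "one_mismatch"):
            instance = [
                sorted(IUPAC[c])[rng.integers(len(IUPAC[c]))] for c in motif.pattern
            ]
            if tata_class == "one_mismatch":
                pos = int(rng.integers(k))
                disallowed = sorted(set("ACGT") - IUPAC[motif.pattern[pos]])
                instance[pos] = disallowed[rng.integers(len(disallowed))]
            off = int(rng.integers(L - k + 1))
            window[off : off + k] = instance
        seq = "".join(window)
        call = scan_promoter(seq, motif)
        if call.tata_class == tata_class:
            return seq
    raise RuntimeError(f"failed to plant a {tata_class!r} promoter in {max_attempts} attempts")


def plant_utr5(uaug: bool, length: int, rng: np.random.Generator, max_rounds: int = 100) -> str:
    """Draw a 5'UTR of the given length with or without any ATG triplet.

    With ``uaug=True`` (requires length >= 3) one ATG is written at a
    uniform position into a random sequence, so at least one upstream AUG
    is guaranteed (more may occur by chance).  With ``uaug=False`` every
    chance ATG has its G mutated to a non-G base until the sequence scans
    clean; raises if the scrub does not converge.
    """
    if length < 0:
        raise ValueError("length must be non-negative")
    if uaug and length < 3:
        raise ValueError("cannot plant a uAUG in a 5'UTR shorter than 3 nt")
    if length == 0:
        return ""
    seq = list(_random_seq(rng, length))
    if uaug:
        pos = int(rng.integers(length - 2))
        seq[pos : pos + 3] = "ATG"
        return "".join(seq)
    non_g = np.frombuffer(b"ACT", dtype="S1")
    for _ in range(max_rounds):
        s = "".join(seq)
        hits = count_uaug(s).positions
        if not hits:
            return s
        for p in hits:
            seq[p + 2] = rng.choice(non_g).decode()
    raise RuntimeError("failed to scrub ATG triplets from a uAUG-less 5'UTR")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with mean ``mean`` and size ``dispersion``
    (variance = mean + mean^2/dispersion)."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def sample_expression(
    uaug: np.ndarray,
    tata: np.ndarray,
    cds_length: np.ndarray,
    gene_length: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw latent expression and observed count tables for a labeled cohort.

    Latent log-(transcription, mRNA, density) triples come from a Gaussian
    copula calibrated to the configured Spearman targets, with additive
    group shifts; observed tables are negative-binomial counts (ribosome
    footprints, total mRNA reads, Gro-seq reads beyond/inside the first kb)
    and a log-normal tissue matrix.  Returns ``(latent, ribo, groseq,
    tissues)`` frames indexed alongside the input arrays.
    """
    n = len(uaug)
    R = spearman_to_pearson(np.asarray(config.copula_corr, dtype=float))
    L = np.linalg.cholesky(R)
    z = (L @ rng.standard_normal((3, n)))

    shifts = {}
    for name in LATENTS:
        tata_shift = np.where(
            uaug, config.shift_tata[name] * config.tata_shift_damping_uaug, config.shift_tata[name]
        )
        shifts[name] = np.where(uaug, config.shift_uaug[name], 0.0) + np.where(tata, tata_shift, 0.0)

    log_txn = (
        np.log(config.scale_transcription)
        + shifts["transcription"]
        + config.latent_sigma["transcription"] * z[0]
    )
    log_mrna = np.log(config.scale_mrna) + shifts["mrna"] + config.latent_sigma["mrna"] * z[1]
    # density latent is anchored so the median TE is scale_te at the median CDS
    median_cds = float(np.median(cds_length))
    log_density = (
        np.log(config.scale_te / median_cds)
        + shifts["density"]
        + config.latent_sigma["density"] * z[2]
    )

    txn_rate = np.exp(log_txn)  # reads/kb
    mrna_level = np.exp(log_mrna)  # expected reads
    density = np.exp(log_density)  # TE per nt
    te = density * cds_length

    mrna_reads = _nb_counts(rng, mrna_level, config.nb_dispersion)
    footprint_reads = _nb_counts(rng, te * mrna_level, config.nb_dispersion)
    body_kb = np.maximum(gene_length - 1000.0, 0.0) / 1000.0
    reads_beyond = _nb_counts(rng, txn_rate * body_kb, config.nb_dispersion)
    reads_first = _nb_counts(rng, txn_rate * config.pausing_factor, config.nb_dispersion)

    tissue_mu = config.tissue_scale * mrna_level / config.scale_mrna
    eps = rng.standard_normal((n, config.n_tissues))
    tissues = config.tissue_background + tissue_mu[:, None] * np.exp(config.tissue_sigma * eps)

    gene_ids = [f"G{i:06d}" for i in range(n)]
    latent = pd.DataFrame(
        {
            "gene": gene_ids,
            "latent_transcription": txn_rate,
            "latent_mrna": mrna_level,
            "latent_density": density,
            "latent_te": te,
        }
    )
    ribo = pd.DataFrame(
        {"gene": gene_ids, "footprint_reads": footprint_reads, "mrna_reads": mrna_reads}
    )
    groseq = pd.DataFrame(
        {"gene": gene_ids, "reads_beyond_1kb": reads_beyond, "reads_first_1kb": reads_first}
    )
    tissue_df = pd.DataFrame(
        np.round(tissues, 2), index=pd.Index(gene_ids, name="gene"),
        columns=[f"tissue_{t:02d}" for t in range(config.n_tissues)],
    )
    return latent, ribo, groseq, tissue_df


def _split_total(total: int, parts: int, rng: np.random.Generator) -> list[int]:
    """Split ``total`` into ``parts`` positive integers (each part gets 1,
    the remainder is spread multinomially)."""
    if parts == 1:
        return [total]
    extra = rng.multinomial(total - parts, np.full(parts, 1.0 / parts))
    return list((extra + 1).astype(int))


def _assemble_gene(
    gid: str,
    strand: str,
    tx_start: int,
    utr5_len: int,
    cds_len: int,
    utr3_len: int,
    gene_len: int,
    exon_count: int,
    rng: np.random.Generator,
) -> GeneModel:
    """Build a coordinate-consistent GeneModel for planted region lengths.

    Exons partition the spliced mRNA (= utr5+cds+utr3); introns fill the
    remaining genomic span.  CDS genomic bounds map the spliced CDS
    interval through the exon chain, honouring strand orientation (the
    5'UTR sits at the low-coordinate end on +, at the high end on -).
    """
    mrna = utr5_len + cds_len + utr3_len
    k = max(1, min(exon_count, mrna))
    if gene_len < mrna + (k - 1):
        gene_len = mrna + (k - 1)
    exon_lens = _split_total(mrna, k, rng)
    intron_lens = _split_total(gene_len - mrna, k - 1, rng) if k > 1 else []
    exon_starts, exon_ends = [], []
    pos = tx_start
    for i, el in enumerate(exon_lens):
        exon_starts.append(pos)
        exon_ends.append(pos + el)
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    tx_end = exon_ends[-1]

    # spliced CDS interval measured from the genomic-left end of the mRNA
    left_offset = utr5_len if strand == "+" else utr3_len
    cds_lo = _spliced_to_genomic(exon_starts, exon_ends, left_offset)
    cds_hi = _spliced_to_genomic(exon_starts, exon_ends, left_offset + cds_len - 1) + 1
    if cds_len == 0:
        cds_lo = cds_hi = tx_start
    return GeneModel(
        accession=f"NM_{gid}",
        symbol=gid,
        chrom="chrS",
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        cds_start=cds_lo,
        cds_end=cds_hi,
        exon_count=k,
        exon_starts=tuple(exon_starts),
        exon_ends=tuple(exon_ends),
    )


def _spliced_to_genomic(starts: list[int], ends: list[int], offset: int) -> int:
    for s, e in zip(starts, ends):
        if offset < e - s:
            return s + offset
        offset -= e - s
    raise ValueError("spliced offset beyond mRNA length")


@dataclass
class Cohort:
    """In-memory simulated cohort plus its ground truth."""

    config: SimConfig
    genes: list[GeneModel]
    promoters: dict[str, str]
    utr5: dict[str, str]
    utr3: dict[str, str]
    cds: dict[str, str]
    ribo: pd.DataFrame
    groseq: pd.DataFrame
    tissues: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit all cohort files; deterministic byte-for-byte given the frames."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "refflat": outdir / "refflat.tsv",
            "promoters": outdir / "promoters.fa",
            "utr5": outdir / "utr5.fa",
            "utr3": outdir / "utr3.fa",
            "cds": outdir / "cds.fa",
            "ribo": outdir / "ribo.tsv",
            "groseq": outdir / "groseq.tsv",
            "tissues": outdir / "tissues.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_genepred(self.genes, paths["refflat"])
        write_fasta(self.promoters, paths["promoters"])
        write_fasta(self.utr5, paths["utr5"])
        write_fasta(self.utr3, paths["utr3"])
        write_fasta(self.cds, paths["cds"])
        self.ribo.to_csv(paths["ribo"], sep="\t", index=False, lineterminator="\n")
        self.groseq.to_csv(paths["groseq"], sep="\t", index=False, lineterminator="\n")
        self.tissues.to_csv(
            paths["tissues"], sep="\t", float_format="%.2f", lineterminator="\n"
        )
        self.truth.to_csv(
            paths["truth"], sep="\t", index=False, float_format="%.8g", lineterminator="\n"
        )
        return paths


def simulate_cohort(config: SimConfig, outdir: str | Path | None = None) -> Cohort:
    """Generate a labeled synthetic cohort (optionally writing its files).

    Deterministic given ``config.seed``.  Every planted promoter window and
    5'UTR is verified against the corresponding classifier at generation
    time, so the emitted labels are recoverable by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    motif = MotifSpec(pattern=config.motif, max_mismatch=config.max_mismatch)

    u = rng.random(n)
    tata_class = np.where(
        u < config.p_canonical,
        "canonical",
        np.where(u < config.p_canonical + config.p_one_mismatch, "one_mismatch", "tata_less"),
    )
    is_tata = tata_class != "tata_less"
    p_uaug = np.where(is_tata, config.p_uaug_given_tata, config.p_uaug_given_tataless)
    uaug = rng.random(n) < p_uaug

    sigma = config.length_sigma
    w = config.compactness_weight
    z_compact = rng.standard_normal(n)
    lengths: dict[str, np.ndarray] = {}
    group_keys = np.array(
        [
            f"{'uAUG' if a else 'uAUG_less'}/{'tata' if t else 'tata_less'}"
            for a, t in zip(uaug, is_tata)
        ]
    )
    for feat in ("utr5", "utr3", "cds", "gene_length"):
        medians = np.array([config.length_medians[feat][g] for g in group_keys])
        eps = rng.standard_normal(n)
        log_len = np.log(medians) + sigma * (np.sqrt(w) * z_compact + np.sqrt(1 - w) * eps)
        lengths[feat] = np.exp(log_len)

    utr5_len = np.maximum(np.rint(lengths["utr5"]).astype(int), np.where(uaug, 3, 0))
    utr3_len = np.maximum(np.rint(lengths["utr3"]).astype(int), 0)
    cds_len = np.maximum(3 * np.rint(lengths["cds"] / 3.0).astype(int), 6)
    gene_len = np.maximum(np.rint(lengths["gene_length"]).astype(int), 1)
    exon_count = 1 + rng.poisson(gene_len / 3000.0)

    gene_ids = [f"G{i:06d}" for i in range(n)]
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    genes: list[GeneModel] = []
    promoters: dict[str, str] = {}
    utr5_seqs: dict[str, str] = {}
    utr3_seqs: dict[str, str] = {}
    cds_seqs: dict[str, str] = {}
    cursor = 1000
    for i, gid in enumerate(gene_ids):
        gm = _assemble_gene(
            gid,
            str(strands[i]),
            cursor,
            int(utr5_len[i]),
            int(cds_len[i]),
            int(utr3_len[i]),
            int(gene_len[i]),
            int(exon_count[i]),
            rng,
        )
        genes.append(gm)
        cursor = gm.tx_end + 1000
        promoters[gid] = plant_promoter(str(tata_class[i]), rng, motif)
        utr5_seqs[gid] = plant_utr5(bool(uaug[i]), int(utr5_len[i]), rng)
        utr3_seqs[gid] = _random_seq(rng, int(utr3_len[i]))
        body = _random_seq(rng, int(cds_len[i]) - 6)
        cds_seqs[gid] = "ATG" + body + "TAA"

    real_gene_len = np.array([g.gene_length for g in genes])
    real_exons = np.array([g.exon_count for g in genes])
    latent, ribo, groseq, tissues = sample_expression(
        uaug, is_tata, cds_len.astype(float), real_gene_len.astype(float), config, rng
    )

    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "tata_class": tata_class,
            "uaug_class": np.where(uaug, "uAUG", "uAUG_less"),
            "utr5_length": utr5_len,
            "utr3_length": utr3_len,
            "cds_length": cds_len,
            "gene_length": real_gene_len,
            "exon_count": real_exons,
        }
    ).merge(latent, on="gene")

    cohort = Cohort(
        config=config,
        genes=genes,
        promoters=promoters,
        utr5=utr5_seqs,
        utr3=utr3_seqs,
        cds=cds_seqs,
        ribo=ribo,
        groseq=groseq,
        tissues=tissues,
        truth=truth,
    )
    if outdir is not None:
        cohort.write(outdir)
    return cohort
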