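"""Synthetic F1-hybrid study generator with known ground truth.

Emulates the statistical structure of an allele-specific expression
study in budding yeast: four parental strains whose genomes differ by
substitutions at a pairwise density of roughly one variant per 200 bp,
crossed into all six F1 hybrids, each grown in three replicates and
sequenced to give allele-resolved counts.  On top of the neutral
background the generator can plant

* cis effects — a log2 expression offset attached to one strain's
  allele of a gene, visible as allelic imbalance in every hybrid that
  carries it;
* promoter motif instances — a consensus binding site embedded at a
  recorded offset, optionally point-disrupted in one strain (and
  optionally coupled to a cis effect, so that binding differences drive
  expression differences);
* trans activities — per-strain multiplicative activities of a TF
  applied to the expression of its target genes through the partner
  strain's trans environment, which the context-specific expression
  statistic is designed to recover.

Counts are negative binomial with variance mu + phi*mu^2.  All
randomness flows from a single integer seed through fixed per-operation
substreams, so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ase_quant import AlleleCountTable
from .motif_bind import BASES, MotifModel

# fixed substream offsets (single seeded generator, forked per operation)
_SUB_STRAINS = 1
_SUB_PLANT = 2
_SUB_COUNTS = 3
_SUB_READS = 4


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of a synthetic hybrid study; the seed fixes everything."""

    n_genes: int
    n_strains: int = 4
    promoter_len: int = 200
    orf_len: int = 500
    snp_rate: float = 0.005           # pairwise substitution density per bp
    n_replicates: int = 3
    baseline_mean: float = 200.0      # expected counts per allele
    dispersion: float = 0.05          # NB: var = mu + phi mu^2
    frac_cis: float = 0.0
    cis_log2_effect: float = 1.0
    tf_activities: dict = field(default_factory=dict)  # tf -> {strain: x}
    library_size_range: tuple[float, float] | None = None
    baseline_sigma: float = 0.5       # lognormal spread of per-gene baselines
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_strains < 2 or self.promoter_len <= 0 \
                or self.orf_len <= 0 or self.n_replicates <= 0:
            raise SimConfigError("counts and lengths must be positive")
        if not (0 <= self.snp_rate < 1):
            raise SimConfigError("snp_rate must lie in [0, 1)")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be >= 0")
        if self.baseline_mean <= 0:
            raise SimConfigError("baseline_mean must be > 0")
        if not (0 <= self.frac_cis <= 1):
            raise SimConfigError("frac_cis must lie in [0, 1]")

    @property
    def strains(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_strains)]

    @property
    def hybrids(self) -> list[tuple[str, str]]:
        s = self.strains
        return [(s[i], s[j]) for i in range(len(s)) for j in range(i + 1, len(s))]

    @property
    def genes(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    def rng(self, substream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), substream])

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if d["library_size_range"] is not None:
            d["library_size_range"] = list(d["library_size_range"])
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class GroundTruth:
    """What the generator planted, for downstream parameter recovery."""

    genes: list[str]
    strains: list[str]
    cis: pd.DataFrame                       # genes x strains, log2 offsets
    targets: dict[str, list[str]] = field(default_factory=dict)       # tf -> genes
    intact: dict[str, pd.DataFrame] = field(default_factory=dict)     # tf -> genes x strains bool
    plant_offsets: dict[str, dict[str, int]] = field(default_factory=dict)
    tf_activities: dict[str, dict[str, float]] = field(default_factory=dict)

    def cis_effect(self, gene: str, strain1: str, strain2: str) -> float:
        """True log2(allele strain1 / allele strain2) for a hybrid."""
        row = self.cis.loc[gene]
        return float(row[strain1] - row[strain2])

    def to_frame(self) -> pd.DataFrame:
        df = self.cis.copy()
        df.columns = [f"cis_log2_{s}" for s in df.columns]
        for tf, genes in self.targets.items():
            df[f"target_{tf}"] = df.index.isin(genes)
        return df.reset_index(names="gene")


# ---------------------------------------------------------------------------
# sequences


def _per_strain_mutation_rate(pairwise_rate: float) -> float:
    """Independent per-strain substitution rate m giving the requested
    pairwise density: P(differ) = 2m(1-m) + (2/3)m^2 = 2m - (4/3)m^2."""
    if pairwise_rate == 0:
        return 0.0
    return 0.75 * (1.0 - np.sqrt(1.0 - 4.0 * pairwise_rate / 3.0))


def _mutate(rng: np.random.Generator, seq_idx: np.ndarray, rate: float) -> np.ndarray:
    out = seq_idx.copy()
    if rate <= 0:
        return out
    hit = np.nonzero(rng.random(len(seq_idx)) < rate)[0]
    if hit.size:
        # substitute to one of the three other bases, uniformly
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def _decode(idx: np.ndarray) -> str:
    return "".join(BASES[i] for i in idx)


def simulate_strains(config: SimConfig) -> tuple[dict[str, dict[str, dict[str, str]]], GroundTruth]:
    """Generate per-strain promoter/ORF sequences and baseline ground truth.

    Each gene has an ancestral uniform-composition sequence; every strain
    independently substitutes bases at the rate that realizes the
    configured *pairwise* SNP density, so alleles stay equal-length and
    coordinate-aligned.  cis effects (``frac_cis`` of genes, magnitude
    ``cis_log2_effect``, random strain and sign) are drawn here so they
    are part of the same deterministic stream.

    Returns (sequences, truth) with sequences[strain][gene] =
    {"promoter": ..., "orf": ...}.
    """
    rng = config.rng(_SUB_STRAINS)
    m = _per_strain_mutation_rate(config.snp_rate)
    genes, strains = config.genes, config.strains
    sequences: dict[str, dict[str, dict[str, str]]] = {s: {} for s in strains}
    for g in genes:
        anc_prom = rng.integers(0, 4, size=config.promoter_len)
        anc_orf = rng.integers(0, 4, size=config.orf_len)
        for s in strains:
            sequences[s][g] = {
                "promoter": _decode(_mutate(rng, anc_prom, m)),
                "orf": _decode(_mutate(rng, anc_orf, m)),
            }

    cis = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"), columns=strains)
    n_cis = int(round(config.frac_cis * config.n_genes))
    if n_cis:
        chosen = rng.choice(config.n_genes, size=n_cis, replace=False)
        which_strain = rng.integers(0, config.n_strains, size=n_cis)
        signs = rng.choice([-1.0, 1.0], size=n_cis)
        for gi, si, sg in zip(chosen, which_strain, signs):
            cis.iloc[gi, si] = sg * config.cis_log2_effect
    truth = GroundTruth(genes=list(genes), strains=list(strains), cis=cis,
                        tf_activities={tf: dict(act) for tf, act in config.tf_activities.items()})
    return sequences, truth


def plant_motifs(sequences: dict[str, dict[str, dict[str, str]]], motif: MotifModel,
                 target_genes: list[str], truth: GroundTruth,
                 disrupt_in_strain: str | None = None, seed: int = 0,
                 couple_cis_log2: float = 0.0) -> None:
    """Embed one consensus motif instance per target gene's promoter.

    The site goes in at a random recorded offset, identical across
    strains; if ``disrupt_in_strain`` is given, that strain's copy gets a
    single substitution at the motif's highest-information position (its
    consensus base flipped to the least-preferred base).
    ``couple_cis_log2`` additionally lowers the disrupted allele's
    expression by that many log2 units, tying binding loss to a cis
    effect.  Sequences and truth are updated in place.
    """
    strains = truth.strains
    rng = np.random.default_rng([int(seed), _SUB_PLANT])
    some_promoter = next(iter(sequences[strains[0]].values()))["promoter"]
    if motif.length > len(some_promoter):
        raise ValueError("motif longer than promoter")
    missing = [g for g in target_genes if g not in sequences[strains[0]]]
    if missing:
        raise ValueError(f"unknown target genes: {missing[:5]}")

    consensus = motif.consensus()
    hot = motif.max_information_position()
    worst_base = BASES[int(np.argmin(motif.theta[hot]))]
    disrupted = consensus[:hot] + worst_base + consensus[hot + 1:]

    offsets: dict[str, int] = {}
    intact = pd.DataFrame(True, index=pd.Index(target_genes, name="gene"), columns=strains)
    for g in target_genes:
        prom_len = len(sequences[strains[0]][g]["promoter"])
        off = int(rng.integers(0, prom_len - motif.length + 1))
        offsets[g] = off
        for s in strains:
            site = disrupted if s == disrupt_in_strain else consensus
            prom = sequences[s][g]["promoter"]
            sequences[s][g]["promoter"] = prom[:off] + site + prom[off + motif.length:]
        if disrupt_in_strain is not None:
            intact.loc[g, disrupt_in_strain] = False
            if couple_cis_log2:
                truth.cis.loc[g, disrupt_in_strain] -= couple_cis_log2
    truth.targets[motif.name] = sorted(target_genes)
    truth.intact[motif.name] = intact
    truth.plant_offsets[motif.name] = offsets
    truth.tf_activities.setdefault(motif.name, {})


def random_motif(name: str, length: int, rng: np.random.Generator,
                 sharpness: float = 0.85) -> MotifModel:
    """A random sharp motif: one preferred base per position with
    probability ``sharpness``, the rest split evenly."""
    theta = np.full((length, 4), (1.0 - sharpness) / 3.0)
    theta[np.arange(length), rng.integers(0, 4, size=length)] = sharpness
    return MotifModel(name, theta, pseudocount=0.0)


# ---------------------------------------------------------------------------
# counts


def simulate_counts(truth: GroundTruth, config: SimConfig) -> AlleleCountTable:
    """Draw NB allele-resolved counts for every hybrid x allele x replicate.

    Per-gene mean for an allele with parent strain p in hybrid h=(s1,s2):
    column scale x baseline_g x 2^(cis offset of p) x prod_TF
    [activity(TF, s1) * activity(TF, s2)]^target(g, TF).

    The cis offset multiplies only the allele that carries it, so the
    true allelic log2 ratio in a hybrid is cis(p1) - cis(p2).  The trans
    factor is the hybrid's *shared* environment — both parents' TF
    activities acting on both alleles equally — so trans differences
    never create allelic imbalance (the premise that makes ASE a pure
    cis readout) yet still shift a target allele's level between hybrid
    contexts, which is exactly the contrast CSE measures.
    Column totals are drawn uniformly from ``library_size_range``
    (default 0.9-1.1x the nominal total) and the means rescaled to hit
    them in expectation.
    """
    rng = config.rng(_SUB_COUNTS)
    genes, strains = truth.genes, truth.strains
    if list(config.genes) != genes:
        raise ValueError("truth does not cover the configured genes")
    n = len(genes)
    baseline = config.baseline_mean * np.exp(
        rng.normal(0.0, config.baseline_sigma, size=n) - config.baseline_sigma ** 2 / 2)

    lo, hi = config.library_size_range or (0.9 * n * config.baseline_mean,
                                           1.1 * n * config.baseline_mean)
    cis = truth.cis.to_numpy()
    strain_ix = {s: i for i, s in enumerate(strains)}

    # per-gene activity multiplier contributed by one parent's TFs
    def strain_activity(strain: str) -> np.ndarray:
        f = np.ones(n)
        for tf, acts in truth.tf_activities.items():
            a = acts.get(strain, 1.0)
            if a != 1.0 and tf in truth.targets:
                mask = pd.Index(genes).isin(truth.targets[tf])
                f[mask] *= a
        return f

    data = {}
    for s1, s2 in config.hybrids:
        hyb = f"{s1}x{s2}"
        shared_trans = strain_activity(s1) * strain_activity(s2)
        for allele in (s1, s2):
            cis_fac = 2.0 ** cis[:, strain_ix[allele]]
            base = baseline * cis_fac * shared_trans
            for r in range(1, config.n_replicates + 1):
                total = rng.uniform(lo, hi)
                mu = base * (total / base.sum())
                if config.dispersion <= 0:
                    k = rng.poisson(mu)
                else:
                    size = 1.0 / config.dispersion
                    k = rng.negative_binomial(size, size / (size + mu))
                data[(hyb, allele, r)] = k
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    counts.columns = pd.MultiIndex.from_tuples(counts.columns,
                                               names=["hybrid", "allele", "replicate"])
    return AlleleCountTable(counts)


# ---------------------------------------------------------------------------
# reads


def simulate_reads(sequences: dict[str, dict[str, dict[str, str]]],
                   gene_reads: dict[str, dict[str, int]], read_len: int,
                   error_rate: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Draw labelled reads uniformly along each allele's ORF.

    ``gene_reads`` maps gene -> {strain: number of reads}.  Substitution
    errors hit each base independently at ``error_rate``.  Returns a
    frame (gene, allele, start, strand, read) retaining the true labels.
    """
    rng = np.random.default_rng([int(seed), _SUB_READS])
    rows = []
    for gene, per_strain in gene_reads.items():
        for strain, n_reads in per_strain.items():
            orf = sequences[strain][gene]["orf"]
            if read_len > len(orf):
                raise ValueError("read_len exceeds ORF length")
            orf_idx = np.array([BASES.index(b) for b in orf])
            starts = rng.integers(0, len(orf) - read_len + 1, size=n_reads)
            strands = rng.random(n_reads) < 0.5
            for start, minus in zip(starts, strands):
                frag = orf_idx[start:start + read_len].copy()
                if error_rate > 0:
                    hit = np.nonzero(rng.random(read_len) < error_rate)[0]
                    if hit.size:
                        frag[hit] = (frag[hit] + rng.integers(1, 4, size=hit.size)) % 4
                seq = _decode(frag)
                if minus:
                    from .motif_bind import reverse_complement
                    seq = reverse_complement(seq)
                rows.append({"gene": gene, "allele": strain, "start": int(start),
                             "strand": "-" if minus else "+", "read": seq})
    return pd.DataFrame(rows, columns=["gene", "allele", "start", "strand", "read"])


# ---------------------------------------------------------------------------
# orchestration & I/O


@dataclass
class PlantSpec:
    """One motif-planting instruction for :func:`simulate_study`."""

    motif: MotifModel
    n_targets: int
    disrupt_in_strain: str | None = None
    couple_cis_log2: float = 0.0


@dataclass
class StudyData:
    config: SimConfig
    sequences: dict[str, dict[str, dict[str, str]]]
    truth: GroundTruth
    table: AlleleCountTable

    def promoters(self) -> dict[str, dict[str, str]]:
        """gene -> {strain: promoter} view for the binding stage."""
        strains = self.truth.strains
        return {g: {s: self.sequences[s][g]["promoter"] for s in strains}
                for g in self.truth.genes}


def simulate_study(config: SimConfig, plants: list[PlantSpec] | None = None) -> StudyData:
    """End-to-end generation: strains, motif plants, then counts.

    Target genes for each plant are drawn without replacement from genes
    not yet used by an earlier plant (so target sets are disjoint and
    binding signals are not confounded between TFs).
    """
    sequences, truth = simulate_strains(config)
    if plants:
        rng = config.rng(_SUB_PLANT)
        available = list(truth.genes)
        for spec in plants:
            if spec.n_targets > len(available):
                raise ValueError("not enough unassigned genes for plant")
            pick = sorted(rng.choice(len(available), size=spec.n_targets, replace=False))
            chosen = [available[i] for i in pick]
            available = [g for g in available if g not in set(chosen)]
            plant_motifs(sequences, spec.motif, chosen, truth,
                         disrupt_in_strain=spec.disrupt_in_strain,
                         seed=config.seed, couple_cis_log2=spec.couple_cis_log2)
    table = simulate_counts(truth, config)
    return StudyData(config=config, sequences=sequences, truth=truth, table=table)


def write_strain_fastas(sequences, outdir) -> None:
    """One FASTA per strain; record ids 'gene|strain|promoter' / '...|orf'."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for strain, genes in sequences.items():
        with open(outdir / f"{strain}.fasta", "w") as fh:
            for gene in sorted(genes):
                for part in ("promoter", "orf"):
                    fh.write(f">{gene}|{strain}|{part}\n{genes[gene][part]}\n")


def read_strain_fastas(paths) -> dict[str, dict[str, dict[str, str]]]:
    """Inverse of :func:`write_strain_fastas` (accepts a list of paths)."""
    from Bio import SeqIO

    sequences: dict[str, dict[str, dict[str, str]]] = {}
    for path in paths:
        for record in SeqIO.parse(str(path), "fasta"):
            gene, strain, part = record.id.split("|")
            sequences.setdefault(strain, {}).setdefault(gene, {})[part] = str(record.seq)
    return sequences
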