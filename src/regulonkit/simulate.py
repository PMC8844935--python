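"""Coupled synthetic fixtures with planted ground truth.

Generates everything the analysis consumes — a gene annotation with
divergent promoter pairs, a random genome with motifs planted at binding
sites, per-replicate/per-epitope summit lists with positional jitter and
imperfect detection, read 5' positions for pileup, and a two-genotype FPKM
matrix with planted fold changes — together with the truth tables the
pipeline is expected to recover.

Defaults echo the structure of a real repressor regulon dataset: ~14% of
genes bound, class proportions 2/10/4/8/2/74 % over
class1/class2/class3_up/class3_down/class4/none, ~35% of bound promoters
with homotypic site clusters (60% for TF genes), 90% per-epitope detection,
20 bp summit jitter, 3 replicates at 20% FPKM CV, planted |log2FC| of 3.

Determinism: one seed; independent child generators (numpy SeedSequence
spawning) for annotation, regulon and cobinding draws, so each stage is
reproducible standalone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .expression import ExpressionMatrix
from .genome import GeneModel, GenomeAnnotation
from .motifs import DEFAULT_MOTIFS, IUPAC, IupacMotif
from .occupancy import ReadStart
from .peaks import PromoterAssignment, ReconciledPeak, Summit
from .integrate import assign_regulatory_class

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic regulon; see module docstring for intent."""

    seed: int
    # genome / annotation
    n_chroms: int = 4
    chrom_len: int = 2_000_000
    n_genes: int = 1000
    fraction_divergent: float = 0.1
    gene_len_range: tuple = (1000, 2500)
    gene_spacing: int = 5000
    divergent_gap_range: tuple = (1800, 2100)
    tf_fraction: float = 0.06
    n_categories: int = 8
    # regulatory classes
    class_proportions: dict = field(
        default_factory=lambda: {
            "class1": 0.02,
            "class2": 0.10,
            "class3_up": 0.04,
            "class3_down": 0.08,
            "class4": 0.02,
            "none": 0.74,
        }
    )
    # binding sites and summits
    summit_jitter_sd: float = 20.0
    jitter_clip: int = 50
    detection_prob: float = 0.9
    multi_site_prob: float = 0.35
    tf_multi_site_prob: float = 0.6
    max_sites: int = 4
    n_decoy_summits: int = 30
    epitopes: tuple = ("HA", "GFP")
    n_chip_replicates: int = 2
    # motifs
    motif_plant_probs: dict = field(
        default_factory=lambda: {"SYGGRG": 0.5, "motif2": 0.3, "motif4": 0.2}
    )
    # expression
    log2fc: float = 3.0
    fpkm_ln_mean: float = 3.0
    fpkm_ln_sd: float = 1.0
    fpkm_floor: float = 2.0
    replicate_cv: float = 0.2
    n_replicates: int = 3
    class2_low_fpkm: float = 5.0
    class2_high_fpkm: float = 100.0
    # reads
    reads_per_site: int = 50
    background_read_rate: float = 2e-5  # reads per bp of genome
    extsize: int = 200
    # cobinding
    cobind_n_promoters: int = 400
    cobound_fraction: float = 0.5
    heterodimer_sd: float = 15.0
    heterodimer_n: int = 500

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class proportions sum to {total}, not 1")
        for name, p in [
            ("fraction_divergent", self.fraction_divergent),
            ("detection_prob", self.detection_prob),
            ("multi_site_prob", self.multi_site_prob),
            ("tf_multi_site_prob", self.tf_multi_site_prob),
            ("cobound_fraction", self.cobound_fraction),
            ("tf_fraction", self.tf_fraction),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.summit_jitter_sd < 0 or self.heterodimer_sd < 0:
            raise ConfigError("jitter sd must be >= 0")

    # child RNGs: 0 = annotation, 1 = regulon, 2 = cobinding
    def rng(self, stream: int) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return np.random.default_rng(children[stream])

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["gene_len_range"] = list(self.gene_len_range)
        d["divergent_gap_range"] = list(self.divergent_gap_range)
        d["epitopes"] = list(self.epitopes)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("gene_len_range", "divergent_gap_range", "epitopes"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown simulation config field(s): {sorted(bad)}")
        return cls(**d)


@dataclass
class SimulationTruth:
    """Planted parameters and labels the pipeline must recover."""

    genes: pd.DataFrame  # per-gene truth incl. bound flag and class
    sites: pd.DataFrame  # per-site positions and planted motifs
    config: SimulationConfig


class AnnotationSim(NamedTuple):
    annotation: GenomeAnnotation
    tf_flags: dict
    categories: dict
    divergent_pairs: list  # list of (gene_id, gene_id)


class RegulonSim(NamedTuple):
    summits: dict  # sample_id -> list[Summit]
    genome: dict  # chrom -> sequence string
    reads: list
    expression: ExpressionMatrix
    truth: SimulationTruth


class CobindingSim(NamedTuple):
    factor_a: list  # PromoterAssignment
    factor_b: list
    reference_distances: np.ndarray
    truth: pd.DataFrame  # gene_id, label


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimulationConfig) -> AnnotationSim:
    """Random gene layout with divergent pairs and >= spacing elsewhere."""
    rng = config.rng(0)
    n_pairs = int(round(config.n_genes * config.fraction_divergent / 2))
    n_singles = config.n_genes - 2 * n_pairs
    units = ["pair"] * n_pairs + ["single"] * n_singles
    rng.shuffle(units)

    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_sizes = {c: config.chrom_len for c in chroms}
    cursors = {c: 3000 for c in chroms}
    genes: list[GeneModel] = []
    divergent_pairs: list[tuple[str, str]] = []
    gid = 0
    ci = 0

    def next_id() -> str:
        nonlocal gid
        gid += 1
        return f"gene_{gid:04d}"

    lo_len, hi_len = config.gene_len_range
    for unit in units:
        length1 = int(rng.integers(lo_len, hi_len))
        spacing = config.gene_spacing + int(rng.integers(0, 1000))
        if unit == "pair":
            gap = int(rng.integers(*config.divergent_gap_range))
            length2 = int(rng.integers(lo_len, hi_len))
            footprint = length1 + gap + length2 + spacing
        else:
            footprint = length1 + spacing
        # find a chromosome with room
        tries = 0
        while cursors[chroms[ci]] + footprint > config.chrom_len - 3000:
            ci += 1
            tries += 1
            if ci >= len(chroms):
                raise ConfigError(
                    "genes do not fit the configured chromosomes; "
                    "increase chrom_len/n_chroms or reduce n_genes"
                )
        chrom = chroms[ci]
        c = cursors[chrom]
        if unit == "pair":
            g1 = GeneModel(next_id(), chrom, "-", c, c + length1, c + length1 - 1)
            lo2 = c + length1 + gap
            g2 = GeneModel(next_id(), chrom, "+", lo2, lo2 + length2, lo2)
            genes.extend([g1, g2])
            divergent_pairs.append((g1.gene_id, g2.gene_id))
            cursors[chrom] = lo2 + length2 + spacing
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            atg = c if strand == "+" else c + length1 - 1
            genes.append(GeneModel(next_id(), chrom, strand, c, c + length1, atg))
            cursors[chrom] = c + length1 + spacing

    tf_flags = {g.gene_id: bool(rng.random() < config.tf_fraction) for g in genes}

    # categories correlated with the (later-drawn) class would couple streams;
    # instead each category prefers a regulatory class and membership is
    # resolved against intended classes drawn here, so one generator suffices.
    from .integrate import REG_CLASSES

    props = config.class_proportions
    classes = list(props)
    intended = rng.choice(classes, size=len(genes), p=[props[c] for c in classes])
    intended_map = dict(zip((g.gene_id for g in genes), intended))

    categories: dict[str, set] = {}
    for k in range(config.n_categories):
        label = f"pathway_{k + 1:02d}"
        preferred = REG_CLASSES[k % len(REG_CLASSES)]
        for g in genes:
            p = 0.5 if intended_map[g.gene_id] == preferred else 0.05
            if rng.random() < p:
                categories.setdefault(g.gene_id, set()).add(label)

    annotation = GenomeAnnotation(genes, chrom_sizes)
    annotation._intended_classes = intended_map  # consumed by simulate_regulon
    return AnnotationSim(annotation, tf_flags, categories, divergent_pairs)


# ---------------------------------------------------------------------------
# regulon


def _site_offsets(rng: np.random.Generator, n: int) -> list[int]:
    """n signed ATG distances in [-1900, 199], pairwise >= 300 bp apart."""
    slots = rng.choice(np.arange(-1900, 101, 400), size=n, replace=False)
    return sorted(int(s + rng.integers(0, 100)) for s in slots)


def _realize_iupac(rng: np.random.Generator, pattern: str) -> str:
    return "".join(IUPAC[c][rng.integers(0, len(IUPAC[c]))] for c in pattern)


def simulate_regulon(
    config: SimulationConfig,
    sim: AnnotationSim,
    motifs: tuple = DEFAULT_MOTIFS,
) -> RegulonSim:
    """Plant sites, summits, motifs, reads and expression for one regulon.

    Binding truth is geometric: after sites are placed for genes of bound
    intended classes, a gene counts as truly bound when any planted site
    falls inside its promoter window — so a site in a shared bidirectional
    promoter marks both genes bound, and the truth class is recomputed from
    (bound, planted DE direction).
    """
    rng = config.rng(1)
    annotation = sim.annotation
    genes = annotation.genes
    intended = annotation._intended_classes

    # ---- binding sites ----
    site_rows = []
    for g in genes:
        if intended[g.gene_id] not in ("class1", "class2", "class4"):
            continue
        p_multi = config.tf_multi_site_prob if sim.tf_flags[g.gene_id] else config.multi_site_prob
        n_sites = int(rng.integers(2, config.max_sites + 1)) if rng.random() < p_multi else 1
        for d in _site_offsets(rng, n_sites):
            pos = g.atg + d if g.strand == "+" else g.atg - d
            site_rows.append({"gene_id": g.gene_id, "chrom": g.chrom, "pos": int(pos)})
    sites = pd.DataFrame(site_rows, columns=["gene_id", "chrom", "pos"])

    # geometric boundness from true site positions
    trees = annotation.promoter_trees()
    bound_genes: set[str] = set()
    site_gene_hits: list[set] = []
    for _, row in sites.iterrows():
        hits = {iv.data for iv in trees[row["chrom"]][row["pos"]]}
        site_gene_hits.append(hits)
        bound_genes |= hits
    n_sites_true = {g.gene_id: 0 for g in genes}
    for hits in site_gene_hits:
        for gid in hits:
            n_sites_true[gid] += 1

    # ---- summit observations per epitope x replicate ----
    summits: dict[str, list[Summit]] = {
        f"{ep}_rep{r + 1}": []
        for ep in config.epitopes
        for r in range(config.n_chip_replicates)
    }

    def observe(chrom: str, pos: int, sample: str) -> None:
        jit = int(np.clip(round(rng.normal(0, config.summit_jitter_sd)), -config.jitter_clip, config.jitter_clip))
        obs = int(np.clip(pos + jit, 0, annotation.chrom_sizes[chrom] - 1))
        height = float(np.exp(rng.normal(3.0, 0.5)))
        summits[sample].append(Summit(chrom, obs, height, sample))

    for _, row in sites.iterrows():
        for ep in config.epitopes:
            if rng.random() < config.detection_prob:
                for r in range(config.n_chip_replicates):
                    observe(row["chrom"], row["pos"], f"{ep}_rep{r + 1}")

    # decoy summits well away from any promoter window (distal/other regions)
    pad = config.jitter_clip + 10
    n_decoys = config.n_decoy_summits
    placed = 0
    while placed < n_decoys:
        chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
        pos = int(rng.integers(1000, config.chrom_len - 1000))
        if trees[chrom].overlaps(pos - pad, pos + pad + 1):
            continue
        for ep in config.epitopes:
            for r in range(config.n_chip_replicates):
                observe(chrom, pos, f"{ep}_rep{r + 1}")
        placed += 1

    # ---- genome with planted motifs ----
    genome_arrays = {
        c: rng.integers(0, 4, size=config.chrom_len).astype(np.uint8)
        for c in annotation.chrom_sizes
    }
    planted_motifs: list[str] = []
    base_index = {b: i for i, b in enumerate("ACGT")}
    for si, row in sites.iterrows():
        names = []
        for k, m in enumerate(motifs):
            prob = config.motif_plant_probs.get(m.name, 0.0)
            if rng.random() < prob:
                word = _realize_iupac(rng, m.pattern)
                start = int(row["pos"]) - 50 + k * 12 + int(rng.integers(0, 6))
                start = max(0, min(config.chrom_len - len(word), start))
                arr = genome_arrays[row["chrom"]]
                arr[start : start + len(word)] = [base_index[b] for b in word]
                names.append(m.name)
        planted_motifs.append("|".join(names))
    sites = sites.assign(planted_motifs=planted_motifs) if len(sites) else sites.assign(planted_motifs=pd.Series(dtype=str))
    genome = {c: BASES[arr].tobytes().decode() for c, arr in genome_arrays.items()}

    # ---- reads ----
    reads: list[ReadStart] = []
    for _, row in sites.iterrows():
        clen = annotation.chrom_sizes[row["chrom"]]
        for _ in range(config.reads_per_site):
            if rng.random() < 0.5:
                p = int(row["pos"]) - int(rng.integers(0, config.extsize))
                strand = "+"
            else:
                p = int(row["pos"]) + int(rng.integers(0, config.extsize))
                strand = "-"
            reads.append(ReadStart(row["chrom"], int(np.clip(p, 0, clen - 1)), strand))
    n_bg = int(round(config.background_read_rate * config.n_chroms * config.chrom_len))
    for _ in range(n_bg):
        chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
        reads.append(
            ReadStart(
                chrom,
                int(rng.integers(0, config.chrom_len)),
                "+" if rng.random() < 0.5 else "-",
            )
        )

    # ---- expression ----
    de_direction = {}
    for g in genes:
        cls = intended[g.gene_id]
        de_direction[g.gene_id] = {"class1": 1, "class3_up": 1, "class3_down": -1, "class4": -1}.get(cls, 0)
    baselines = {}
    for g in genes:
        cls = intended[g.gene_id]
        if cls == "class2":
            level = config.class2_low_fpkm if rng.random() < 0.5 else config.class2_high_fpkm
            baselines[g.gene_id] = level * float(np.exp(rng.normal(0, 0.3)))
        else:
            baselines[g.gene_id] = max(
                config.fpkm_floor, float(np.exp(rng.normal(config.fpkm_ln_mean, config.fpkm_ln_sd)))
            )
    cv = config.replicate_cv
    sigma = float(np.sqrt(np.log1p(cv**2)))

    def noisy(mean: float) -> float:
        if sigma == 0:
            return mean
        return mean * float(np.exp(rng.normal(0, sigma) - sigma**2 / 2))

    gene_ids = [g.gene_id for g in genes]
    wt = np.zeros((len(genes), config.n_replicates))
    mut = np.zeros_like(wt)
    for i, g in enumerate(genes):
        base = baselines[g.gene_id]
        shifted = base * 2.0 ** (de_direction[g.gene_id] * config.log2fc)
        for r in range(config.n_replicates):
            wt[i, r] = noisy(base)
            mut[i, r] = noisy(shifted)
    cols = [f"rep{r + 1}" for r in range(config.n_replicates)]
    expression = ExpressionMatrix(
        wt=pd.DataFrame(wt, index=gene_ids, columns=cols),
        mut=pd.DataFrame(mut, index=gene_ids, columns=cols),
    )

    # ---- truth table ----
    dir_status = {1: "up", -1: "down", 0: "unchanged"}
    truth_rows = []
    for g in genes:
        bound = g.gene_id in bound_genes
        truth_rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "atg": g.atg,
                "is_tf": sim.tf_flags[g.gene_id],
                "intended_class": intended[g.gene_id],
                "de_direction": de_direction[g.gene_id],
                "planted_log2fc": de_direction[g.gene_id] * config.log2fc,
                "baseline_fpkm": baselines[g.gene_id],
                "bound": bound,
                "n_sites": n_sites_true[g.gene_id],
                "truth_class": assign_regulatory_class(bound, dir_status[de_direction[g.gene_id]]),
            }
        )
    truth = SimulationTruth(
        genes=pd.DataFrame(truth_rows).set_index("gene_id"),
        sites=sites,
        config=config,
    )
    return RegulonSim(summits, genome, reads, expression, truth)


# ---------------------------------------------------------------------------
# cobinding


def simulate_cobinding(config: SimulationConfig) -> CobindingSim:
    """Two-factor summit sets over shared promoters, plus heterodimer ref.

    Cobound promoters place factor B's summit at A's position plus
    N(0, sd*sqrt(2)) jitter (two independently jittered observations of one
    site); distinct promoters place B uniformly 101-1000 bp away.  The
    heterodimer reference distances are |N(0, sd*sqrt(2))| rounded to bp.
    """
    rng = config.rng(2)
    sd_pair = config.heterodimer_sd * np.sqrt(2.0)
    chrom = "cobind_chr"

    def assignment(gene: str, pos: int, sample: str) -> PromoterAssignment:
        s = Summit(chrom, pos, 1.0, sample)
        peak = ReconciledPeak(chrom, pos, (s,), frozenset({sample}))
        return PromoterAssignment(gene, peak, 0)

    factor_a: list[PromoterAssignment] = []
    factor_b: list[PromoterAssignment] = []
    rows = []
    for i in range(config.cobind_n_promoters):
        gene = f"shared_{i + 1:04d}"
        a_pos = 5000 + i * 5000
        cobound = rng.random() < config.cobound_fraction
        if cobound:
            b_pos = a_pos + int(round(rng.normal(0, sd_pair)))
        else:
            sign = 1 if rng.random() < 0.5 else -1
            b_pos = a_pos + sign * int(rng.integers(101, 1001))
        factor_a.append(assignment(gene, a_pos, "factorA"))
        factor_b.append(assignment(gene, max(0, b_pos), "factorB"))
        rows.append({"gene_id": gene, "label": "cobound" if cobound else "distinct"})
    reference = np.abs(np.round(rng.normal(0, sd_pair, size=config.heterodimer_n)))
    truth = pd.DataFrame(rows, columns=["gene_id", "label"])
    return CobindingSim(factor_a, factor_b, reference, truth)


# ---------------------------------------------------------------------------
# fixture writing


def write_fixture(
    directory: str | Path,
    sim: AnnotationSim,
    regulon: RegulonSim,
    motifs: tuple = DEFAULT_MOTIFS,
) -> dict:
    """Write a complete fixture to disk in plain-text formats.

    Emits GFF3 + chrom sizes, genome FASTA, per-sample summit BED6, read
    BED6, FPKM TSV + sample sheet, motif TSV, category TSV, TF list, truth
    tables, and the simulation config.  Everything round-trips through the
    package's own readers.
    """
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    ann = sim.annotation
    paths: dict[str, Path] = {}

    # GFF3 (1-based inclusive) with gene + CDS
    paths["annotation"] = out / "annotation.gff3"
    with open(paths["annotation"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(ann.genes, key=lambda g: (g.chrom, g.span_lo)):
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.span_lo + 1}\t{g.span_hi}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tsim\tCDS\t{g.span_lo + 1}\t{g.span_hi}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds;Parent={g.gene_id}\n"
            )

    paths["chrom_sizes"] = out / "chrom.sizes"
    with open(paths["chrom_sizes"], "w") as fh:
        for c in sorted(ann.chrom_sizes):
            fh.write(f"{c}\t{ann.chrom_sizes[c]}\n")

    paths["genome"] = out / "genome.fa"
    with open(paths["genome"], "w") as fh:
        for c in sorted(regulon.genome):
            fh.write(f">{c}\n")
            seq = regulon.genome[c]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    summit_dir = out / "summits"
    summit_dir.mkdir(exist_ok=True)
    for sample in sorted(regulon.summits):
        p = summit_dir / f"{sample}.bed"
        paths[f"summits:{sample}"] = p
        with open(p, "w") as fh:
            for s in sorted(regulon.summits[sample], key=lambda s: (s.chrom, s.pos)):
                fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{sample}\t{s.height:.4f}\t.\n")

    paths["reads"] = out / "reads.bed"
    from .occupancy import write_read_starts

    write_read_starts(regulon.reads, paths["reads"])

    paths["expression"] = out / "expression.tsv"
    expr = pd.concat(
        {
            "wt": regulon.expression.wt,
            "mut": regulon.expression.mut,
        },
        axis=1,
    )
    expr.columns = [f"{cond}_{rep}" for cond, rep in expr.columns]
    expr.index.name = "gene_id"
    expr.to_csv(paths["expression"], sep="\t", float_format="%.6g")

    paths["samples"] = out / "samples.tsv"
    with open(paths["samples"], "w") as fh:
        fh.write("sample\tcondition\treplicate\n")
        for cond in ("wt", "mut"):
            for r in range(regulon.expression.n_replicates):
                fh.write(f"{cond}_rep{r + 1}\t{cond}\t{r + 1}\n")

    paths["motifs"] = out / "motifs.tsv"
    with open(paths["motifs"], "w") as fh:
        for m in motifs:
            fh.write(f"{m.name}\t{m.pattern}\n")

    paths["categories"] = out / "categories.tsv"
    with open(paths["categories"], "w") as fh:
        for gene in sorted(sim.categories):
            for lab in sorted(sim.categories[gene]):
                fh.write(f"{gene}\t{lab}\n")

    paths["tf_genes"] = out / "tf_genes.txt"
    with open(paths["tf_genes"], "w") as fh:
        for gene in sorted(g for g, f in sim.tf_flags.items() if f):
            fh.write(gene + "\n")

    paths["truth_genes"] = out / "truth_genes.tsv"
    regulon.truth.genes.to_csv(paths["truth_genes"], sep="\t", float_format="%.6g")
    paths["truth_sites"] = out / "truth_sites.tsv"
    regulon.truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False)

    paths["config"] = out / "config.yaml"
    regulon.truth.config.to_yaml(paths["config"])
    return paths
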