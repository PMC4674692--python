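"""Synthetic multi-condition epigenome with planted ground truth.

Emulates the six-isogenic-line design (one parental reference plus five
endocrine-therapy-resistant derivatives): per-condition binned H3K27ac
coverage with Poisson counts, planted activity-pattern clusters of
candidate regions, planted super-enhancers (dense constituent clusters at
high signal), planted TAD-wide shifts with a punctuated counter-regulated
gene, expression coupled to promoter acetylation by a power law with
lognormal noise, and DNase-cut tracks with centrally depleted, motif-bearing
footprint sites embedded in a generated genome sequence.  Everything is
written in the same plain-text formats the analysis pipeline consumes, and
identical seed + config reproduce byte-identical files.

Chromosome roles (fixed layout): the first chromosome carries the candidate
activity-pattern regions, their genes and the footprint sites; the second
carries the super-enhancers plus typical enhancer peaks; the third is tiled
by TADs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .genome import GenomeLayout, GenomicInterval, GeneModel, RegionSet, ValidationError, write_bed, write_gene_table
from .footprints import PWM
from .signal import SignalTrack

__all__ = ["SimulationConfig", "GroundTruth", "simulate", "emit_pwm"]

DEFAULT_CONDITIONS = ("parental", "tamr", "fulvr", "lted", "ltedt", "ltedf")

# up-in-derived / down-in-derived / line-specific linear activity multipliers,
# reference (parental) always 1
DEFAULT_CLUSTER_SPEC = [
    ((1.0, 4.0, 4.0, 1.0, 1.0, 1.0), 10),
    ((1.0, 1.0, 1.0, 4.0, 4.0, 4.0), 10),
    ((1.0, 0.25, 0.25, 0.25, 0.25, 0.25), 10),
    ((1.0, 1.0, 4.0, 1.0, 4.0, 1.0), 10),
    ((1.0, 4.0, 1.0, 4.0, 1.0, 4.0), 10),
]


@dataclass
class SimulationConfig:
    seed: int
    n_chroms: int = 3
    chrom_length: int = 900_000
    bin_size: int = 200
    n_conditions: int = 6
    condition_labels: tuple = DEFAULT_CONDITIONS
    n_regions: int = 60
    region_width: int = 1000
    region_pitch: int = 14_000  # > default stitch distance, keeps regions unstitched
    cluster_spec: list = field(default_factory=lambda: [list(x) for x in DEFAULT_CLUSTER_SPEC])
    background_rate: float = 25.0
    region_amplitude_sd: float = 0.4  # lognormal sd of per-region amplitude
    # SEs: (count, constituents per SE, constituent gap bp, signal multiplier)
    se_count: int = 8
    se_constituents: int = 5
    se_spacing: int = 3000
    se_multiplier: float = 15.0
    n_typical_peaks: int = 30
    typical_multiplier: float = 2.0
    # TADs
    n_tads: int = 11
    tad_width: int = 80_000
    shifted_tad_index: int = 3
    tad_shift_factor: float = 1.5
    punctuated_tad_index: int = 7
    punctuated_tad_factor: float = 0.8
    punctuated_local_factor: float = 4.0
    shift_condition: str = "lted"
    # expression link: FPKM = a * activity^b * lognormal(0, sd)
    expression_scale: float = 1.0
    expression_exponent: float = 1.0
    expression_noise_sd: float = 0.2
    # footprints
    n_footprint_sites: int = 100
    motif_consensus: str = "TCACGTGA"
    center_depletion: float = 0.1
    flank_rate: float = 5.0  # DHS cuts per DHS bin inside accessible chromatin
    dhs_bin_size: int = 10
    footprint_center: int = 20
    footprint_flank: int = 100
    # accessible regions are wide enough to hold many candidate windows, of
    # which only the central, motif-bearing one is depleted (bound)
    accessible_halfwidth: int = 1110

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.background_rate < 0 or self.flank_rate < 0:
            raise ValidationError("rates must be >= 0")
        if self.n_conditions != len(self.condition_labels):
            self.condition_labels = tuple(
                ["parental"] + [f"resistant{i}" for i in range(1, self.n_conditions)]
            )
        for pattern, count in self.cluster_spec:
            if len(pattern) != self.n_conditions:
                raise ValidationError("cluster pattern length must equal n_conditions")
        if sum(c for _, c in self.cluster_spec) > self.n_regions:
            raise ValidationError("cluster region counts exceed n_regions")
        if self.n_chroms < 3:
            raise ValidationError("layout needs >= 3 chromosomes (regions, SEs, TADs)")
        last_region_end = 10_000 + (self.n_regions - 1) * self.region_pitch + self.region_width
        se_extent = self.se_count * (
            self.se_constituents * (self.region_width + self.se_spacing) + 30_000
        )
        if last_region_end > self.chrom_length or se_extent > self.chrom_length:
            raise ValidationError("planted structures exceed chromosome length")
        if self.n_tads * self.tad_width > self.chrom_length:
            raise ValidationError("TADs exceed chromosome length")
        gap = self.region_pitch - self.region_width
        if self.accessible_halfwidth >= 1500 or 9000 + self.accessible_halfwidth > gap:
            raise ValidationError("accessible regions do not fit between planted regions")

    @property
    def reference(self) -> str:
        return self.condition_labels[0]

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["condition_labels"] = list(d["condition_labels"])
        return d


@dataclass
class GroundTruth:
    region_clusters: dict[str, int]  # region key -> planted pattern index (0 = background)
    cluster_patterns: list[list[float]]
    se_spans: list[str]  # planted SE span keys
    shifted_tad: str
    punctuated_tad: str
    punctuated_gene: str
    gene_patterns: dict[str, int]  # gene -> planted pattern index
    footprint_sites: list[str]  # center-window keys, depleted condition only
    motif_positions: list[tuple[str, int]]
    footprint_condition: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["motif_positions"] = [tuple(x) for x in d["motif_positions"]]
        return cls(**d)


def emit_pwm(consensus: str, pseudo: float, path=None, name: str = "motif") -> PWM:
    """Column-stochastic position-frequency matrix with 1 - 3*pseudo on the
    consensus base and pseudo elsewhere; optionally written to disk."""
    pwm = PWM.from_consensus(consensus, pseudo, name=name)
    if path is not None:
        pwm.write(path)
    return pwm


def _interval_key(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def simulate(config: SimulationConfig, outdir) -> tuple[dict[str, Path], GroundTruth]:
    """Generate the synthetic epigenome under `outdir` and return the file
    paths plus the planted ground truth (also serialized as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    b = config.bin_size
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genome = GenomeLayout({c: config.chrom_length for c in chroms})
    n_bins = config.chrom_length // b
    region_chrom, se_chrom, tad_chrom = chroms[0], chroms[1], chroms[2]

    # ---- planted candidate regions with activity patterns -----------------
    patterns = [list(p) for p, _ in config.cluster_spec]
    labels: list[int] = []
    for idx, (_, count) in enumerate(config.cluster_spec, start=1):
        labels += [idx] * count
    labels += [0] * (config.n_regions - len(labels))  # background pattern
    region_ivs, region_keys = [], []
    for i in range(config.n_regions):
        start = 10_000 + i * config.region_pitch
        iv = GenomicInterval(region_chrom, start, start + config.region_width)
        region_ivs.append(iv)
        region_keys.append(iv.key())
    amplitudes = (
        rng.lognormal(0.0, config.region_amplitude_sd, size=config.n_regions)
        if config.region_amplitude_sd > 0
        else np.ones(config.n_regions)
    )

    # ---- planted SEs and typical peaks on the SE chromosome ---------------
    se_spans, se_constituent_ivs = [], []
    se_pitch = config.se_constituents * (config.region_width + config.se_spacing) + 30_000
    for s in range(config.se_count):
        base = 10_000 + s * se_pitch
        members = []
        for k in range(config.se_constituents):
            st = base + k * (config.region_width + config.se_spacing)
            members.append(GenomicInterval(se_chrom, st, st + config.region_width))
        se_constituent_ivs.append(members)
        se_spans.append(_interval_key(se_chrom, members[0].start, members[-1].end))
    typical_base = 10_000 + config.se_count * se_pitch
    typical_ivs = []
    for t in range(config.n_typical_peaks):
        st = typical_base + t * config.region_pitch
        if st + config.region_width > config.chrom_length:
            raise ValidationError("typical peaks exceed chromosome length")
        typical_ivs.append(GenomicInterval(se_chrom, st, st + config.region_width))

    # ---- TADs --------------------------------------------------------------
    tad_ivs = [
        GenomicInterval(tad_chrom, i * config.tad_width, (i + 1) * config.tad_width)
        for i in range(config.n_tads)
    ]
    shifted_tad = tad_ivs[config.shifted_tad_index]
    punct_tad = tad_ivs[config.punctuated_tad_index]
    punct_start = punct_tad.start + config.tad_width // 2
    punct_region = GenomicInterval(tad_chrom, punct_start, punct_start + config.region_width)

    # ---- genes -------------------------------------------------------------
    genes: list[GeneModel] = []
    gene_patterns: dict[str, int] = {}
    for i, iv in enumerate(region_ivs):
        if i % 2 == 0:  # every other region is promoter-proximal to a gene
            gid = f"gene{i:04d}"
            genes.append(GeneModel(gid, region_chrom, iv.midpoint, iv.midpoint + 2000, "+"))
            gene_patterns[gid] = labels[i]
    punct_gene = GeneModel(
        "gene_punct", tad_chrom, punct_region.midpoint, punct_region.midpoint + 2000, "+"
    )
    genes.append(punct_gene)

    # ---- per-condition H3K27ac mean fields then Poisson draws --------------
    shift_j = list(config.condition_labels).index(config.shift_condition)
    mean_fields: dict[str, dict[str, np.ndarray]] = {}
    for j, cond in enumerate(config.condition_labels):
        field_ = {c: np.full(n_bins, config.background_rate) for c in chroms}
        for i, iv in enumerate(region_ivs):
            mult = patterns[labels[i] - 1][j] if labels[i] > 0 else 1.0
            field_[region_chrom][iv.start // b : iv.end // b] = (
                config.background_rate * mult * amplitudes[i]
            )
        for members in se_constituent_ivs:
            for m in members:
                field_[se_chrom][m.start // b : m.end // b] = (
                    config.background_rate * config.se_multiplier
                )
        for t in typical_ivs:
            field_[se_chrom][t.start // b : t.end // b] = (
                config.background_rate * config.typical_multiplier
            )
        if j == shift_j:
            sl = slice(shifted_tad.start // b, shifted_tad.end // b)
            field_[tad_chrom][sl] = field_[tad_chrom][sl] * config.tad_shift_factor
            # the punctuated-TAD factor is the NET aggregate ratio: the gene's
            # local excess is compensated by the remaining bins so the domain
            # as a whole measures punctuated_tad_factor vs the reference
            n_tad_bins = config.tad_width // b
            n_local_bins = config.region_width // b
            f_rest = (
                config.punctuated_tad_factor * n_tad_bins
                - n_local_bins * config.punctuated_local_factor
            ) / (n_tad_bins - n_local_bins)
            if f_rest <= 0:
                raise ValidationError("punctuated local excess exceeds its TAD budget")
            sl = slice(punct_tad.start // b, punct_tad.end // b)
            field_[tad_chrom][sl] = field_[tad_chrom][sl] * f_rest
            sl = slice(punct_region.start // b, punct_region.end // b)
            field_[tad_chrom][sl] = config.background_rate * config.punctuated_local_factor
        mean_fields[cond] = field_

    track_paths = {}
    for cond in config.condition_labels:
        data = {c: rng.poisson(mean_fields[cond][c]).astype(float) for c in chroms}
        track = SignalTrack(cond, b, data)
        p = outdir / f"{cond}.h3k27ac.bedgraph"
        track.to_bedgraph(p)
        track_paths[cond] = p

    # ---- expression: FPKM = a * activity^b * lognormal noise ---------------
    fpkm_rows = []
    all_genes = sorted(genes, key=lambda g: g.gene_id)
    for g in all_genes:
        row = [g.gene_id]
        for j, cond in enumerate(config.condition_labels):
            if g.gene_id == "gene_punct":
                mult = config.punctuated_local_factor if j == shift_j else 1.0
                amp = 1.0
            else:
                i = int(g.gene_id[4:])
                mult = patterns[labels[i] - 1][j] if labels[i] > 0 else 1.0
                amp = amplitudes[i]
            activity = config.background_rate * mult * amp
            noise = rng.lognormal(0.0, config.expression_noise_sd) if config.expression_noise_sd > 0 else 1.0
            fpkm = config.expression_scale * activity**config.expression_exponent * noise
            row.append(f"{fpkm:.6g}")
        fpkm_rows.append(row)

    # ---- DHS cut tracks + genome sequence with embedded motifs -------------
    db = config.dhs_bin_size
    dhs_bins = config.chrom_length // db
    acc_half = config.accessible_halfwidth
    site_centers = []
    slot = 0
    for i in range(config.n_regions):
        for off in (3000, 6000, 9000):
            if slot >= config.n_footprint_sites:
                break
            center = 10_000 + i * config.region_pitch + config.region_width + off
            site_centers.append(center)
            slot += 1
    if slot < config.n_footprint_sites:
        raise ValidationError("not enough room on the region chromosome for footprint sites")
    accessible_ivs = [
        GenomicInterval(region_chrom, c - acc_half, c + acc_half) for c in site_centers
    ]
    fp_condition = config.shift_condition
    dhs_paths = {}
    fp_center_keys = []
    for cond in (config.reference, fp_condition):
        field_ = {c: np.full(dhs_bins, 0.0) for c in chroms}
        for center in site_centers:
            a = field_[region_chrom]
            a[(center - acc_half) // db : (center + acc_half) // db] = config.flank_rate
            if cond == fp_condition:
                c0 = (center - config.footprint_center // 2) // db
                c1 = (center + config.footprint_center // 2) // db
                a[c0:c1] = config.flank_rate * config.center_depletion
        data = {c: rng.poisson(field_[c]).astype(float) for c in chroms}
        p = outdir / f"{cond}.dhs.bedgraph"
        SignalTrack(cond, db, data).to_bedgraph(p)
        dhs_paths[cond] = p
    for center in site_centers:
        h = config.footprint_center // 2
        fp_center_keys.append(_interval_key(region_chrom, center - h, center + h))

    motif = config.motif_consensus.upper()
    seqs = {}
    motif_positions = []
    for c in chroms:
        arr = rng.integers(0, 4, size=config.chrom_length)
        seq = np.array(list("ACGT"))[arr]
        if c == region_chrom:
            for center in site_centers:
                start = center - len(motif) // 2
                seq[start : start + len(motif)] = list(motif)
                motif_positions.append((c, start))
        seqs[c] = "".join(seq)

    # ---- write remaining files ---------------------------------------------
    paths: dict[str, Path] = dict(track_paths)
    paths.update({f"dhs_{k}": v for k, v in dhs_paths.items()})

    genome_path = outdir / "genome.sizes.tsv"
    genome.to_tsv(genome_path)
    paths["genome"] = genome_path

    all_peaks = RegionSet(
        region_ivs + [m for members in se_constituent_ivs for m in members] + typical_ivs
        + [punct_region],
        label="candidate_regions",
        genome=genome,
    )
    paths["regions"] = outdir / "regions.bed"
    write_bed(all_peaks, paths["regions"])

    paths["genes"] = outdir / "genes.tsv"
    write_gene_table(all_genes, paths["genes"])

    paths["tads"] = outdir / "tads.bed"
    write_bed(RegionSet(tad_ivs, genome=genome), paths["tads"])

    paths["expression"] = outdir / "expression.tsv"
    with open(paths["expression"], "w") as fh:
        fh.write("gene_id\t" + "\t".join(config.condition_labels) + "\n")
        for row in fpkm_rows:
            fh.write("\t".join(row) + "\n")

    paths["accessible"] = outdir / "accessible.bed"
    write_bed(RegionSet(accessible_ivs, genome=genome), paths["accessible"])

    paths["fasta"] = outdir / "genome.fasta"
    with open(paths["fasta"], "w") as fh:
        for c in chroms:
            fh.write(f">{c}\n")
            s = seqs[c]
            for k in range(0, len(s), 80):
                fh.write(s[k : k + 80] + "\n")

    paths["pwm"] = outdir / "motif.pwm"
    emit_pwm(motif, 0.05, paths["pwm"], name="planted_motif")

    truth = GroundTruth(
        region_clusters={k: labels[i] for i, k in enumerate(region_keys)},
        cluster_patterns=patterns,
        se_spans=se_spans,
        shifted_tad=shifted_tad.key(),
        punctuated_tad=punct_tad.key(),
        punctuated_gene="gene_punct",
        gene_patterns=gene_patterns,
        footprint_sites=fp_center_keys,
        motif_positions=motif_positions,
        footprint_condition=fp_condition,
    )
    paths["ground_truth"] = outdir / "ground_truth.json"
    truth.to_json(paths["ground_truth"])
    return paths, truth
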