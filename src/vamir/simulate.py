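"""Seeded synthetic data with full ground truth for every pipeline stage.

The generator emulates the statistical structure a small-RNA analysis
assumes: a background genome with embedded structural-RNA / gene-model /
repeat features, planted miRNA hairpin precursors (arm + loop +
reverse-complement arm with controlled defects) whose matures receive
log-normal read counts, low-frequency single-substitution (miR-SNP) and
terminal-shift (miR-LD) variant reads, miRNA* reads at a fraction of the
mature, and adapter-flanked reads drawn per annotation-category fractions
with a 24-nt-dominant length profile.  Every read traces to one truth
record, and a fixed seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import ConfigError, revcomp

__all__ = ["SimConfig", "SimTruth", "SimBundle", "simulate_genome", "simulate_library", "simulate"]

_BASES = np.array(list("ACGT"))

# Default redundant-read category fractions: the published category
# distribution of the Amur grape library (2-decimal percentages / 100).
DEFAULT_CATEGORY_FRACTIONS = {
    "exon_antisense": 0.0160,
    "exon_sense": 0.0326,
    "intron_antisense": 0.0237,
    "intron_sense": 0.0466,
    "miRNA": 0.0545,
    "rRNA": 0.0983,
    "repeat": 0.0579,
    "siRNA": 0.1549,
    "snRNA": 0.0013,
    "snoRNA": 0.0007,
    "tRNA": 0.0446,
    "unann": 0.4689,
}

# 24-nt-dominant length profile; 20-24 nt carry ~85% of reads and the
# 24-nt class ~37%, echoing the canonical Dicer product distribution.
DEFAULT_LENGTH_PROFILE = {
    15: 0.010, 16: 0.012, 17: 0.015, 18: 0.020, 19: 0.030,
    20: 0.060, 21: 0.150, 22: 0.140, 23: 0.130, 24: 0.3694,
    25: 0.020, 26: 0.015, 27: 0.010, 28: 0.008, 29: 0.006, 30: 0.0046,
}

FAMILY_CYCLE = [
    "miR156", "miR159", "miR160", "miR164", "miR166", "miR167",
    "miR169", "miR171", "miR172", "miR319", "miR396", "miR398",
]


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 60_000
    n_mirnas: int = 24
    expression_meanlog: float = 4.0
    expression_sdlog: float = 1.6
    snp_rate: float = 56 / 126      # fraction of miRNAs carrying a planted miR-SNP
    ld_rate: float = 43 / 126       # fraction carrying a planted miR-LD
    variant_fraction: float = 0.03  # variant reads as fraction of wild-type reads
    star_fraction: float = 0.10     # star reads as fraction of mature reads
    category_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_FRACTIONS))
    length_profile: dict = field(default_factory=lambda: dict(DEFAULT_LENGTH_PROFILE))
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    n_decoys: int = 20
    n_sirna_loci: int = 30
    low_quality_fraction: float = 0.005

    def validate(self) -> None:
        if abs(sum(self.category_fractions.values()) - 1.0) > 1e-9:
            raise ConfigError("category_fractions must sum to 1")
        if abs(sum(self.length_profile.values()) - 1.0) > 1e-6:
            raise ConfigError("length_profile must sum to 1")
        for name in ("snp_rate", "ld_rate", "variant_fraction", "star_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")


@dataclass
class SimTruth:
    mirnas: pd.DataFrame       # planted precursors, matures, stars, counts, variants
    features: pd.DataFrame     # planted annotation features
    decoys: pd.DataFrame       # shuffled non-hairpin windows + their tag
    reads: pd.DataFrame = None  # per unique insert: sequence, category, count, source
    n_raw_reads: int = 0
    n_low_quality: int = 0


@dataclass
class SimBundle:
    config: SimConfig
    genome: dict
    truth: SimTruth
    reads: list = field(default_factory=list)  # (read_id, sequence, quality list)
    zones: dict = field(default_factory=dict)  # zone name -> (0-based start, length)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _markov_shuffle(rng: np.random.Generator, seq: str) -> str:
    """Composition-preserving shuffle: resample from the sequence's
    first-order Markov chain (keeps dinucleotide statistics in
    expectation, destroys long-range pairing structure)."""
    trans = {b: [] for b in "ACGT"}
    for a, b in zip(seq, seq[1:]):
        trans[a].append(b)
    out = [seq[0]]
    for _ in range(len(seq) - 1):
        nxt = trans.get(out[-1]) or trans[seq[0]]
        if not nxt:
            nxt = list("ACGT")
        out.append(nxt[rng.integers(0, len(nxt))])
    return "".join(out)


def _build_precursor(rng: np.random.Generator):
    """arm + loop + revcomp(arm) with defects planted away from the
    mature/star duplex so the planted mature folds cleanly on the 5p arm."""
    arm_len = int(rng.integers(40, 56))
    mature_len = int(rng.integers(20, 23))
    # offset >= 3 keeps the star's 2-nt 3' overhang shift inside the precursor
    offset = int(rng.integers(3, arm_len - mature_len - 3))
    arm = _rand_seq(rng, arm_len)
    loop = _rand_seq(rng, int(rng.integers(10, 16)))
    comp = list(revcomp(arm))
    # candidate defect sites: revcomp-copy indices whose arm partner is
    # outside the mature +- 4 nt duplex neighbourhood
    protected = range(max(0, offset - 4), min(arm_len, offset + mature_len + 4))
    free = [k for k in range(arm_len) if (arm_len - 1 - k) not in protected]
    n_def = int(rng.integers(0, 3))
    for k in rng.choice(len(free), size=min(n_def, len(free)), replace=False):
        pos = free[int(k)]
        comp[pos] = str(rng.choice([b for b in "ACGT" if b != comp[pos]]))
    precursor = arm + loop + "".join(comp)
    mature = arm[offset : offset + mature_len]
    # star: duplex partner span with canonical 2-nt 3' overhangs
    n_pre = len(precursor)
    partner = lambda p: n_pre - 1 - p  # arm index p pairs revcomp-copy position
    lo = partner(offset + mature_len - 1) + 2
    hi = min(n_pre - 1, partner(offset) + 2)
    star = precursor[lo : hi + 1]
    return precursor, mature, offset, star


def simulate_genome(config: SimConfig) -> SimBundle:
    """Background genome with embedded non-overlapping features, hairpin
    precursors and shuffled decoy windows; placements recorded in truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    feature_plan = [
        ("rRNA", 2, 300), ("tRNA", 4, 80), ("snRNA", 3, 150), ("snoRNA", 3, 120),
        ("repeat", 3, 400),
        ("exon_sense", 4, 600), ("exon_antisense", 4, 600),
        ("intron_sense", 4, 500), ("intron_antisense", 4, 500),
    ]
    mirna_rows, feature_rows, decoy_rows = [], [], []
    segments: list[str] = []
    pos = 0  # 0-based cursor

    def emit(seq: str) -> int:
        nonlocal pos
        start = pos
        segments.append(seq)
        pos += len(seq)
        return start

    def gap():
        emit(_rand_seq(rng, int(rng.integers(30, 80))))

    gap()
    for cat, n, size in feature_plan:
        track = cat.split("_")[0]
        for i in range(n):
            start = emit(_rand_seq(rng, size))
            feature_rows.append(
                {"category": cat, "track": track, "chrom": "chr1",
                 "start": start + 1, "end": start + size, "strand": "+"}
            )
            gap()
    # hairpin precursors
    fam_members: dict[str, int] = {}
    for i in range(config.n_mirnas):
        precursor, mature, offset, star = _build_precursor(rng)
        fam = FAMILY_CYCLE[(i // 2) % len(FAMILY_CYCLE)]
        member = chr(ord("a") + fam_members.get(fam, 0))
        fam_members[fam] = fam_members.get(fam, 0) + 1
        start = emit(precursor)
        mirna_rows.append(
            {
                "mirna_id": f"vam-{fam}{member}", "family": fam,
                "mature_seq": mature, "star_seq": star,
                "precursor_seq": precursor, "chrom": "chr1",
                "precursor_start": start + 1, "precursor_end": start + len(precursor),
                "mature_start": start + offset + 1,
                "mature_end": start + offset + len(mature), "strand": "+",
            }
        )
        gap()
    # decoys: composition-preserving shuffles of hairpin-like windows
    for i in range(config.n_decoys):
        precursor, mature, offset, _ = _build_precursor(rng)
        shuffled = _markov_shuffle(rng, precursor)
        tag = shuffled[offset : offset + len(mature)]
        start = emit(shuffled)
        decoy_rows.append(
            {
                "decoy_id": f"decoy{i + 1:03d}", "chrom": "chr1",
                "start": start + 1, "end": start + len(shuffled),
                "tag_seq": tag, "tag_start": start + offset + 1,
                "tag_end": start + offset + len(tag),
            }
        )
        gap()
    # dedicated siRNA zone (duplex tags, no annotation features)
    sirna_zone_start = emit(_rand_seq(rng, max(1500, config.n_sirna_loci * 40)))
    sirna_zone_len = pos - sirna_zone_start
    gap()
    # dedicated unannotated zone
    unann_zone_start = emit(_rand_seq(rng, 6000))
    unann_zone_len = pos - unann_zone_start
    if pos > config.genome_length:
        raise ConfigError(
            f"genome_length {config.genome_length} too small for requested features ({pos} nt used)"
        )
    emit(_rand_seq(rng, config.genome_length - pos))
    genome = {"chr1": "".join(segments)}
    truth = SimTruth(
        mirnas=pd.DataFrame(mirna_rows),
        features=pd.DataFrame(feature_rows),
        decoys=pd.DataFrame(decoy_rows),
    )
    return SimBundle(
        config,
        genome,
        truth,
        zones={
            "siRNA": (sirna_zone_start, sirna_zone_len),
            "unann": (unann_zone_start, unann_zone_len),
        },
    )


def _draw_lengths(rng: np.random.Generator, profile: dict, n: int) -> np.ndarray:
    lengths = np.array(sorted(profile))
    probs = np.array([profile[k] for k in lengths], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(lengths, size=n, p=probs)


def simulate_library(bundle: SimBundle) -> SimBundle:
    """Draw the read library over the planted genome; complete the truth.

    Category read counts follow ``category_fractions`` of the total
    implied by the log-normal miRNA expression draw; variant and star
    reads are emitted for flagged miRNAs; every read is wrapped with the
    3' adapter and given synthetic qualities.
    """
    config = bundle.config
    rng = np.random.default_rng(config.seed + 1)
    truth = bundle.truth
    genome = bundle.genome["chr1"]
    zones = bundle.zones

    m = truth.mirnas
    n_mir = len(m)
    counts = np.maximum(
        2, np.round(rng.lognormal(config.expression_meanlog, config.expression_sdlog, n_mir))
    ).astype(int)
    star_counts = np.round(config.star_fraction * counts).astype(int)
    has_snp = rng.random(n_mir) < config.snp_rate
    has_ld = rng.random(n_mir) < config.ld_rate

    inserts: list[tuple[str, str, str]] = []  # (sequence, category, source_id) per UNIQUE insert
    insert_counts: list[int] = []

    snp_pos = np.full(n_mir, -1)
    snp_alt = np.full(n_mir, "", dtype=object)
    snp_seq = np.full(n_mir, "", dtype=object)
    snp_reads = np.zeros(n_mir, dtype=int)
    ld_d5 = np.zeros(n_mir, dtype=int)
    ld_d3 = np.zeros(n_mir, dtype=int)
    ld_seq = np.full(n_mir, "", dtype=object)
    ld_reads = np.zeros(n_mir, dtype=int)

    for i in range(n_mir):
        row = m.iloc[i]
        mature = row.mature_seq
        inserts.append((mature, "miRNA", row.mirna_id))
        insert_counts.append(int(counts[i]))
        if star_counts[i] > 0:
            inserts.append((row.star_seq, "star", row.mirna_id))
            insert_counts.append(int(star_counts[i]))
        n_var = max(1, int(round(config.variant_fraction * counts[i])))
        if has_snp[i]:
            p = int(rng.integers(2, len(mature)))  # internal, 1-based position p
            ref = mature[p - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            vs = mature[: p - 1] + alt + mature[p:]
            snp_pos[i], snp_alt[i], snp_seq[i], snp_reads[i] = p, alt, vs, n_var
            inserts.append((vs, "miRNA", f"{row.mirna_id}:SNP"))
            insert_counts.append(n_var)
        if has_ld[i]:
            # templated terminal shift: +-1-2 nt at one end, drawn from the precursor
            end5 = bool(rng.random() < 0.5)
            delta = int(rng.choice([-2, -1, 1, 2]))
            off = row.mature_start - row.precursor_start  # 0-based offset in precursor
            pre = row.precursor_seq
            if end5:
                delta = min(delta, off)  # extension templated from the precursor
                new_off = off - delta
                vs = pre[new_off : off + len(mature)]
                d5, d3 = delta, 0
            else:
                vs = pre[off : off + len(mature) + delta]
                d5, d3 = 0, delta
            if vs != mature and len(vs) >= 15:
                ld_d5[i], ld_d3[i], ld_seq[i], ld_reads[i] = d5, d3, vs, n_var
                inserts.append((vs, "miRNA", f"{row.mirna_id}:LD"))
                insert_counts.append(n_var)

    mirna_total = int(counts.sum() + snp_reads.sum() + ld_reads.sum())
    total_reads = int(round(mirna_total / config.category_fractions["miRNA"]))

    feat = truth.features
    for cat in sorted(config.category_fractions):
        if cat == "miRNA":
            continue
        n_cat = int(round(config.category_fractions[cat] * total_reads))
        if cat == "unann":
            n_cat = max(0, n_cat - int(star_counts.sum()))
        if n_cat == 0:
            continue
        if cat == "siRNA":
            zone_start, zone_len = zones["siRNA"]
            locus_pos = zone_start + rng.choice(
                zone_len - 30, size=config.n_sirna_loci, replace=False
            )
            locus_len = rng.integers(21, 25, config.n_sirna_loci)
            duplex = []
            for p, ln in zip(locus_pos, locus_len):
                frag = genome[p : p + ln]
                duplex.append((frag, f"sirna@{p + 1}+"))
                duplex.append((revcomp(frag), f"sirna@{p + 1}-"))
            picks = rng.integers(0, len(duplex), n_cat)
            uniq, cnts = np.unique(picks, return_counts=True)
            for u, c in zip(uniq, cnts):
                seq, src = duplex[int(u)]
                inserts.append((seq, "siRNA", src))
                insert_counts.append(int(c))
            continue
        if cat == "unann":
            zone_start, zone_len = zones["unann"]
            lengths = _draw_lengths(rng, config.length_profile, n_cat)
            starts = zone_start + rng.integers(0, zone_len - 31, n_cat)
            frags = [genome[s : s + ln] for s, ln in zip(starts, lengths)]
            seq_counts: dict[str, int] = {}
            for f in frags:
                seq_counts[f] = seq_counts.get(f, 0) + 1
            for seq in sorted(seq_counts):
                inserts.append((seq, "unann", "unann_zone"))
                insert_counts.append(seq_counts[seq])
            continue
        # track-feature categories (rRNA, tRNA, ..., exon/intron sense & antisense)
        rows = feat[feat.category == cat].reset_index(drop=True)
        lengths = _draw_lengths(rng, config.length_profile, n_cat)
        pick_feat = rng.integers(0, len(rows), n_cat)
        seq_counts = {}
        antisense = cat.endswith("_antisense")
        for k in range(n_cat):
            fr = rows.iloc[int(pick_feat[k])]
            ln = int(lengths[k])
            s = int(rng.integers(fr.start - 1, fr.end - ln + 1))
            fragment = genome[s : s + ln]
            if antisense:
                fragment = revcomp(fragment)
            seq_counts[fragment] = seq_counts.get(fragment, 0) + 1
        for seq in sorted(seq_counts):
            inserts.append((seq, cat, cat))
            insert_counts.append(seq_counts[seq])

    # decoy mature-like tags (truth category: unann; flagged as decoys)
    for _, d in truth.decoys.iterrows():
        inserts.append((d.tag_seq, "unann", d.decoy_id))
        insert_counts.append(15)

    m = m.assign(
        reads=counts, star_reads=star_counts, has_snp=has_snp, has_ld=has_ld,
        snp_position=snp_pos, snp_alt=snp_alt, snp_variant_seq=snp_seq, snp_reads=snp_reads,
        ld_delta5=ld_d5, ld_delta3=ld_d3, ld_variant_seq=ld_seq, ld_reads=ld_reads,
    )
    truth.mirnas = m
    truth.reads = pd.DataFrame(
        {
            "sequence": [x[0] for x in inserts],
            "category": [x[1] for x in inserts],
            "source": [x[2] for x in inserts],
            "count": insert_counts,
        }
    )

    # materialize adapter-flanked reads with synthetic qualities
    seqs = truth.reads.sequence.to_numpy()
    cnts = truth.reads["count"].to_numpy()
    order = rng.permutation(int(cnts.sum()))
    expanded = np.repeat(np.arange(len(seqs)), cnts)[order]
    n_low = int(round(config.low_quality_fraction * len(expanded)))
    low_idx = set(rng.choice(len(expanded), size=n_low, replace=False).tolist()) if n_low else set()
    reads = []
    for ridx, ins_idx in enumerate(expanded):
        seq = seqs[ins_idx] + config.adapter3
        if ridx in low_idx:
            qual = [10] * len(seq)
        else:
            qual = [40] * len(seq)
        reads.append((f"read{ridx + 1}", seq, qual))
    bundle.reads = reads
    truth.n_raw_reads = len(reads)
    truth.n_low_quality = n_low
    return bundle


def simulate(config: SimConfig | None = None) -> SimBundle:
    """Convenience: genome + library in one call."""
    bundle = simulate_genome(config or SimConfig())
    return simulate_library(bundle)


# ---------------------------------------------------------------- file output

def write_bundle(bundle: SimBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, tracks GFF3, reads FASTQ, truth TSVs and the
    config echo; byte-identical under a fixed seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    genome_path = out / "genome.fa"
    with open(genome_path, "w") as fh:
        for chrom in sorted(bundle.genome):
            fh.write(f">{chrom}\n")
            seq = bundle.genome[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    paths["genome"] = genome_path

    gff_path = out / "tracks.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in bundle.truth.features.iterrows():
            fh.write(
                f"{row.chrom}\tvamir_sim\t{row.track}\t{row.start}\t{row.end}\t.\t{row.strand}\t.\t"
                f"ID={row.category}\n"
            )
    paths["gff"] = gff_path

    fastq_path = out / "reads.fastq"
    with open(fastq_path, "w") as fh:
        for rid, seq, qual in bundle.reads:
            qstr = "".join(chr(q + 33) for q in qual)
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")
    paths["reads"] = fastq_path

    mature_path = out / "mature.fa"
    with open(mature_path, "w") as fh:
        for _, row in bundle.truth.mirnas.iterrows():
            fh.write(f">{row.mirna_id}\n{row.mature_seq}\n")
    paths["mature"] = mature_path

    for name, df in [
        ("truth_mirnas", bundle.truth.mirnas),
        ("truth_features", bundle.truth.features),
        ("truth_decoys", bundle.truth.decoys),
        ("truth_reads", bundle.truth.reads),
    ]:
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p

    cfg_path = out / "sim_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(asdict(bundle.config), fh, sort_keys=True)
    paths["config"] = cfg_path
    return paths
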