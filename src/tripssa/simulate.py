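"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the full measurement chain of the reporter assay on a
toy genome: transposon insertions tied to unique 20-nt barcodes, chromatin
feature tracks over 200-bp windows, inverse-PCR read pairs for mapping,
UMI-amplicon read pairs under linear-amplification (UMI-LA, 50 cycles from
the top strand only) or exponential (UMI-PCR, 6 cycles from both strands)
semantics, and methylation-calibration oligonucleotides.  Repair events are
drawn per barcode and per replicate: NHEJ keeps both repeats, SSA resolves
the central mismatch toward the longer-flap strand with a tunable
probability, or leaves it unresolved.  Template-strand cytosine deamination
during UMI-LA converts template C to T at a methylation-dependent per-cycle
rate and propagates to all later copies, which is what makes discordant UMI
pools a usable methylation signature.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so outputs (including FASTQ byte content) are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tripssa.construct import (
    BARCODE_LENGTH,
    CUT_SITES,
    F_SEGMENT_CPGS,
    MISMATCH_OFFSET,
    WATERMARK,
    MismatchSpec,
    build_reference_construct,
    complement,
    longer_flap_strand,
    revcomp,
)

NUCLEOTIDES = np.array(list("ACGT"))

# Read geometry: both amplicon reads extend the F-segment midpoint by 3 nt.
FWD_CORE_START = MISMATCH_OFFSET - 3  # 73: right half plus 3 nt past midpoint
REV_CORE_END = MISMATCH_OFFSET + 3  # 79: left half plus 3 nt past midpoint
UMI_LENGTH = 18

VECTOR_STUB = "GTGTATGTAAACTTCCGACTTCAAC"[:25]
OLIGO_CORE = "GATCGATC"
OLIGO_FLANK = 12
OLIGO_CPG_C = OLIGO_FLANK + 3  # the C of the central CpG, methylatable


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment."""

    seed: int = 1
    n_barcodes: int = 1000
    n_replicates: int = 4
    construct: str = "G:T"
    cut_site: str = "iscei"
    mode: str = "PCR"  # LA | PCR
    control: bool = False

    # Repair model
    ssa_fraction: float = 0.7
    unrepaired_fraction: float = 0.05
    strand_bias: float = 0.7  # P(resolve toward the longer-flap strand)
    pre_recombined_fraction: float = 0.05  # clonal barcodes seen in controls

    # Amplification
    la_cycles: int = 50
    pcr_cycles: int = 6
    umis_per_barcode: float = 8.0  # mean of sequenced UMIs per barcode
    reads_per_umi: float = 3.0  # geometric mean, >=1; single-read pairs are filtered

    # Error model
    sequencing_error: float = 0.001  # per base per read
    polymerase_error: float = 1e-4  # per base per UMI copy
    deamination_meth: float = 3e-4  # per cycle per methylated C (UMI-LA)
    deamination_unmeth: float = 3e-5  # per cycle per unmethylated C (UMI-LA)
    synthesis_error: float = 0.002  # per base per oligo molecule
    template_switch_rate: float = 0.001  # per UMI

    # Genome / chromatin
    chrom_sizes: dict = field(
        default_factory=lambda: {
            "chr1": 80_000,
            "chr2": 60_000,
            "chr3": 40_000,
            "chrX": 50_000,
        }
    )
    half_dose_chroms: tuple = ("chrX",)
    expressed_weight: float = 1.0  # 1.35 reproduces the transcription excess
    window_size: int = 200
    n_tracks: int = 78
    planted_track: int | None = None
    planted_effect: float = 0.0  # additive shift of the local strand bias
    methylated_fraction: float = 0.8
    meth_protect_track: int | None = None
    meth_protect_factor: float = 0.3

    # iPCR
    ipcr_reads_per_barcode: int = 5
    ipcr_flank: int = 50
    ipcr_truncate_fraction: float = 0.0  # barcodes emitted with 13 nt only

    def rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, *key)))


# -- sequence helpers ---------------------------------------------------------


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(NUCLEOTIDES[rng.integers(0, 4, size=length)])


def inject_substitutions(
    rng: np.random.Generator, seq: str, rate: float
) -> str:
    """Substitute bases at the given per-base rate (never the same base)."""
    if rate <= 0:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    positions = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(0, 3)]
    return "".join(out)


# -- genome, insertions, chromatin -------------------------------------------


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Toy genome with annotated expressed/silent/intergenic blocks.

    Autosomes and one half-dose chromosome (haploid-X analogue) are tiled
    with a repeating [expressed, intergenic, silent, intergenic] block
    pattern.  A 1-kb segment of chr1 is duplicated into chr2 so that
    multi-mapping fragments exist.
    """
    rng = config.rng(0)
    min_size = 2 * config.ipcr_flank + 100
    genome = {}
    for chrom, size in config.chrom_sizes.items():
        if size < min_size:
            raise ValueError(f"{chrom} shorter than read length budget ({size})")
        genome[chrom] = random_dna(rng, size)
    if "chr1" in genome and "chr2" in genome:
        dup = genome["chr1"][10_000:11_000]
        genome["chr2"] = genome["chr2"][:20_000] + dup + genome["chr2"][21_000:]

    pattern = [("expressed", 4000), ("intergenic", 3000), ("silent", 4000), ("intergenic", 3000)]
    rows = []
    for chrom, size in config.chrom_sizes.items():
        pos = 0
        i = 0
        while pos < size:
            category, length = pattern[i % len(pattern)]
            end = min(pos + length, size)
            rows.append({"chrom": chrom, "start": pos, "end": end, "category": category})
            pos = end
            i += 1
    annotation = pd.DataFrame(rows)
    return genome, annotation


def _category_at(annotation: pd.DataFrame, chrom: str, pos: int) -> str:
    grp = annotation[annotation["chrom"] == chrom]
    hit = grp[(grp["start"] <= pos) & (pos < grp["end"])]
    return hit.iloc[0]["category"] if len(hit) else "intergenic"


def simulate_insertions(
    genome: dict[str, str], annotation: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Insertion table: one unique 20-nt barcode per mappable locus.

    Positions are drawn uniformly per bp, weighted by chromosome dose (0.5
    on the haploid analogue) and optionally by ``expressed_weight`` in
    expressed genes.  Loci whose downstream fragment would be unmappable
    (too short before the next CATG, or multi-mapping) are redrawn, which
    mirrors restricting to the mappable genome.
    """
    from tripssa.mapping import ToyAligner

    rng = config.rng(1)
    aligner = ToyAligner(genome)
    chroms = list(config.chrom_sizes)
    doses = np.array(
        [0.5 if c in config.half_dose_chroms else 1.0 for c in chroms]
    )
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes * doses
    probs /= probs.sum()
    max_weight = max(config.expressed_weight, 1.0)

    barcodes: set[str] = set()
    taken: set[tuple[str, int]] = set()
    rows = []
    attempts = 0
    while len(rows) < config.n_barcodes:
        attempts += 1
        if attempts > 200 * config.n_barcodes:
            raise RuntimeError("cannot place insertions; genome too constrained")
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        pos = int(rng.integers(0, config.chrom_sizes[chrom] - config.ipcr_flank - 30))
        category = _category_at(annotation, chrom, pos)
        weight = config.expressed_weight if category == "expressed" else 1.0
        if rng.random() >= weight / max_weight:
            continue
        if (chrom, pos) in taken:
            continue
        fragment = genome[chrom][pos : pos + config.ipcr_flank]
        cut = fragment.find("CATG")
        if cut >= 0:
            fragment = fragment[:cut]
        if len(fragment) < 20:
            continue
        if len(aligner.map_fragment(fragment)) != 1:
            continue
        while True:
            barcode = random_dna(rng, BARCODE_LENGTH)
            if barcode not in barcodes:
                break
        barcodes.add(barcode)
        taken.add((chrom, pos))
        rows.append(
            {
                "barcode": barcode,
                "chrom": chrom,
                "pos": pos,
                "strand": "+",
                "category": category,
            }
        )
    return pd.DataFrame(rows)


def simulate_chromatin_features(
    genome: dict[str, str], config: SimConfig
) -> pd.DataFrame:
    """Binary occupancy for 78 tracks over 200-bp windows, plus GC content.

    Each track covers a random fraction of windows (1-10%, echoing sparse
    chromatin marks); GC content is computed from the toy genome in 10-kb
    and 1-Mb windows (clipped at chromosome ends).
    """
    rng = config.rng(2)
    coverages = rng.uniform(0.01, 0.10, size=config.n_tracks)
    rows = []
    for chrom, seq in genome.items():
        size = len(seq)
        gc = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_gc = (gc == ord("G")) | (gc == ord("C"))
        for start in range(0, size, config.window_size):
            rows.append((chrom, start))
    features = pd.DataFrame(rows, columns=["chrom", "start"])
    n = len(features)
    track_matrix = (
        rng.random((n, config.n_tracks)) < coverages[None, :]
    ).astype(np.int8)
    for j in range(config.n_tracks):
        features[f"track_{j}"] = track_matrix[:, j]

    gc10, gc1m = [], []
    gc_cache = {c: None for c in genome}
    for chrom, grp in features.groupby("chrom", sort=False):
        seq = genome[chrom]
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        csum = np.concatenate([[0], np.cumsum(is_gc)])
        for start in grp["start"]:
            mid = start + config.window_size // 2
            for half, out in ((5_000, gc10), (500_000, gc1m)):
                lo, hi = max(0, mid - half), min(len(seq), mid + half)
                out.append((csum[hi] - csum[lo]) / (hi - lo))
    features["gc_10kb"] = gc10
    features["gc_1Mb"] = gc1m
    return features


def window_of(config: SimConfig, pos: int) -> int:
    return (pos // config.window_size) * config.window_size


def attach_features(
    insertions: pd.DataFrame, features: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Inherit the full chromatin profile of the window holding each insertion."""
    ins = insertions.copy()
    ins["window_start"] = [window_of(config, p) for p in ins["pos"]]
    merged = ins.merge(
        features,
        left_on=["chrom", "window_start"],
        right_on=["chrom", "start"],
        how="left",
        suffixes=("", "_w"),
    ).drop(columns=["start"])
    return merged


# -- repair outcomes ----------------------------------------------------------


def simulate_repair_outcomes(
    insertions: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Per-barcode, per-replicate ground-truth repair events.

    Induced runs draw independently per replicate: NHEJ with probability
    1 - ``ssa_fraction``; otherwise SSA, left unresolved with probability
    ``unrepaired_fraction`` or resolved toward the longer-flap strand with
    probability ``strand_bias`` (plus the planted chromatin effect when
    configured).  Control runs mark a ``pre_recombined_fraction`` of
    barcodes as clonally recombined with one fixed outcome across all
    replicates; the rest stay uncut.
    """
    rng = config.rng(3)
    cut = CUT_SITES[config.cut_site]
    favored = longer_flap_strand(cut)
    other = "bottom" if favored == "top" else "top"

    planted = np.zeros(len(insertions))
    track_col = (
        f"track_{config.planted_track}" if config.planted_track is not None else None
    )
    if track_col is not None and track_col in insertions.columns:
        planted = insertions[track_col].to_numpy() * config.planted_effect

    methylated = _draw_methylation(insertions, config, rng)

    rows = []
    if config.control:
        clonal = rng.random(len(insertions)) < config.pre_recombined_fraction
        clonal_strand = np.where(rng.random(len(insertions)) < 0.5, "top", "bottom")
        for i, row in enumerate(insertions.itertuples()):
            for rep in range(config.n_replicates):
                if clonal[i]:
                    rows.append(
                        (row.barcode, rep, "SSA", True, clonal_strand[i], True, methylated[i])
                    )
                else:
                    rows.append((row.barcode, rep, "uncut", False, None, False, methylated[i]))
    else:
        for i, row in enumerate(insertions.itertuples()):
            p_favored = float(np.clip(config.strand_bias + planted[i], 0.0, 1.0))
            for rep in range(config.n_replicates):
                if rng.random() >= config.ssa_fraction:
                    rows.append((row.barcode, rep, "NHEJ", True, None, False, methylated[i]))
                elif rng.random() < config.unrepaired_fraction:
                    rows.append((row.barcode, rep, "SSA", False, None, False, methylated[i]))
                else:
                    strand = favored if rng.random() < p_favored else other
                    rows.append((row.barcode, rep, "SSA", True, strand, False, methylated[i]))
    return pd.DataFrame(
        rows,
        columns=[
            "barcode",
            "replicate",
            "pathway",
            "repaired",
            "resolved_strand",
            "pre_recombined",
            "methylated",
        ],
    )


def _draw_methylation(
    insertions: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    p = np.full(len(insertions), config.methylated_fraction)
    col = (
        f"track_{config.meth_protect_track}"
        if config.meth_protect_track is not None
        else None
    )
    if col is not None and col in insertions.columns:
        p = np.where(
            insertions[col].to_numpy() == 1, p * config.meth_protect_factor, p
        )
    return rng.random(len(insertions)) < p


# -- inverse-PCR reads --------------------------------------------------------


def simulate_ipcr_reads(
    insertions: pd.DataFrame, genome: dict[str, str], config: SimConfig
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Paired iPCR FASTQ records ((name, fwd), (name, rev)) for mapping."""
    rng = config.rng(4)
    fwd_reads, rev_reads = [], []
    truncate = rng.random(len(insertions)) < config.ipcr_truncate_fraction
    for i, row in enumerate(insertions.itertuples()):
        flank = genome[row.chrom][row.pos : row.pos + config.ipcr_flank]
        barcode = row.barcode[:13] if truncate[i] else row.barcode
        for r in range(config.ipcr_reads_per_barcode):
            fwd = barcode + WATERMARK + "CATG" + flank[:30]
            rev = VECTOR_STUB + flank
            fwd = inject_substitutions(rng, fwd, config.sequencing_error)
            rev = inject_substitutions(rng, rev, config.sequencing_error)
            name = f"ipcr:{i}:{r}"
            fwd_reads.append((name, fwd))
            rev_reads.append((name, rev))
    return fwd_reads, rev_reads


# -- UMI amplicon reads -------------------------------------------------------


def _molecule_cores(outcome, spec: MismatchSpec) -> tuple[str, str, bool]:
    """(fwd_core, rev_core, overlapping) read templates of one molecule.

    Cores are in top-strand orientation: the forward core is the right half
    of the (distal) segment from position 73, the reverse core the left half
    of the (proximal) segment up to position 79.  For SSA products both
    cores come from the single repaired segment, so reads overlap.
    """
    construct = build_reference_construct(spec, "A" * BARCODE_LENGTH)
    if outcome.pathway in ("NHEJ", "uncut"):
        return (
            construct.right_repeat[FWD_CORE_START:],
            construct.left_repeat[:REV_CORE_END],
            False,
        )
    # SSA: resolved molecules have one definite top-strand base.
    if outcome.repaired:
        strand = outcome.resolved_strand
        top_base = (
            spec.top_allele if strand == "top" else complement(spec.bottom_allele)
        )
        seg = construct.repeat_with_top_base(top_base)
        return seg[FWD_CORE_START:], seg[:REV_CORE_END], True
    # Unresolved heteroduplex: strand chosen per UMI at amplification time.
    return "", "", True


def simulate_umi_amplicon_reads(
    outcomes: pd.DataFrame,
    config: SimConfig,
    replicate: int,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], pd.DataFrame]:
    """UMI-amplicon read pairs for one replicate run.

    One template molecule enters the reaction per barcode.  In LA mode every
    sampled UMI is a copy of the top strand made at a uniformly drawn cycle;
    template cytosines deaminate per cycle at a methylation-dependent rate
    and all later copies inherit the C-to-T change.  In PCR mode each UMI
    samples one of the two template strands, so unresolved heteroduplexes
    emit UMIs carrying both alleles.  Polymerase errors are drawn once per
    UMI copy, sequencing errors per read; a configurable fraction of UMIs is
    chimerically re-emitted under a second barcode (template switching).
    """
    rng = config.rng(5, replicate, 0 if config.mode == "LA" else 1, int(config.control))
    spec = MismatchSpec.from_code(config.construct)
    run = outcomes[outcomes["replicate"] == replicate]
    barcodes = run["barcode"].tolist()
    fwd_reads, rev_reads, manifest = [], [], []

    la = config.mode == "LA"
    cycles = config.la_cycles if la else config.pcr_cycles

    for idx, outcome in enumerate(run.itertuples()):
        fwd_core, rev_core, _ = _molecule_cores(outcome, spec)
        hetero = outcome.pathway == "SSA" and not outcome.repaired
        n_umis = max(1, int(rng.poisson(config.umis_per_barcode)))

        # Template-strand deamination schedule (LA only): per C position the
        # first cycle at which the template C has turned to T, if ever.
        deam_fwd = deam_rev = None
        if la:
            rate_m, rate_u = config.deamination_meth, config.deamination_unmeth
            deam_fwd = _deamination_schedule(
                rng, fwd_core or "", FWD_CORE_START, outcome.methylated, rate_m, rate_u, cycles
            )
            deam_rev = _deamination_schedule(
                rng, rev_core or "", 0, outcome.methylated, rate_m, rate_u, cycles
            )

        for u in range(n_umis):
            umi = random_dna(rng, UMI_LENGTH)
            cycle = int(rng.integers(1, cycles + 1))
            if hetero:
                if la:
                    strand = "top"  # LA copies the top strand only
                else:
                    strand = "top" if rng.random() < 0.5 else "bottom"
                top_base = (
                    spec.top_allele if strand == "top" else complement(spec.bottom_allele)
                )
                construct = build_reference_construct(spec, "A" * BARCODE_LENGTH)
                seg = construct.repeat_with_top_base(top_base)
                f_core, r_core = seg[FWD_CORE_START:], seg[:REV_CORE_END]
            else:
                f_core, r_core = fwd_core, rev_core
            if la:
                f_core = _apply_deamination(f_core, FWD_CORE_START, deam_fwd, cycle)
                r_core = _apply_deamination(r_core, 0, deam_rev, cycle)

            fwd_tpl = outcome.barcode + WATERMARK + f_core
            rev_tpl = umi + revcomp(r_core)
            fwd_tpl = inject_substitutions(rng, fwd_tpl, config.polymerase_error)
            rev_tpl = (
                rev_tpl[:UMI_LENGTH]
                + inject_substitutions(rng, rev_tpl[UMI_LENGTH:], config.polymerase_error)
            )

            n_reads = int(rng.geometric(1.0 / config.reads_per_umi))
            targets = [outcome.barcode]
            if rng.random() < config.template_switch_rate and len(barcodes) > 1:
                # Chimeric attachment: the same UMI also shows up under a
                # second barcode, the signature used to detect switching.
                swap = barcodes[int(rng.integers(0, len(barcodes)))]
                if swap != outcome.barcode:
                    targets.append(swap)
            for target in targets:
                fwd_full = target + fwd_tpl[BARCODE_LENGTH:]
                for r in range(n_reads):
                    name = f"amp:{replicate}:{idx}:{u}:{r}:{len(targets) - 1}"
                    fwd_reads.append(
                        (name, inject_substitutions(rng, fwd_full, config.sequencing_error))
                    )
                    rev_reads.append(
                        (name, inject_substitutions(rng, rev_tpl, config.sequencing_error))
                    )
            manifest.append(
                {
                    "replicate": replicate,
                    "barcode": outcome.barcode,
                    "umi": umi,
                    "cycle": cycle,
                    "pathway": outcome.pathway,
                    "repaired": outcome.repaired,
                    "resolved_strand": outcome.resolved_strand,
                    "n_reads": n_reads,
                    "chimeric": len(targets) > 1,
                }
            )
    return fwd_reads, rev_reads, pd.DataFrame(manifest)


def _deamination_schedule(
    rng: np.random.Generator,
    core: str,
    offset: int,
    methylated: bool,
    rate_meth: float,
    rate_unmeth: float,
    cycles: int,
) -> dict[int, int]:
    """First deamination cycle per C position of one template core.

    CpG cytosines of a methylated molecule deaminate at the methylated
    rate; all other cytosines at the unmethylated rate.  Positions are
    F-segment coordinates (``offset`` maps core index 0).
    """
    schedule: dict[int, int] = {}
    cpg_set = set(F_SEGMENT_CPGS)
    for i, base in enumerate(core):
        if base != "C":
            continue
        pos = offset + i
        rate = rate_meth if (methylated and pos in cpg_set) else rate_unmeth
        if rate <= 0:
            continue
        t = int(rng.geometric(rate))
        if t <= cycles:
            schedule[i] = t
    return schedule


def _apply_deamination(core: str, offset: int, schedule, cycle: int) -> str:
    if not schedule:
        return core
    out = list(core)
    for i, t in schedule.items():
        if cycle >= t and out[i] == "C":
            out[i] = "T"
    return "".join(out)


# -- methylation-calibration oligos ------------------------------------------


def simulate_methylation_oligos(
    config: SimConfig, arm: str
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Single-end UMI-LA reads from methylated or unmethylated control oligos.

    Each molecule is ``N12 + GATCGATC + N12``; the central CpG cytosine is
    methylated in the "meth" arm.  Synthesis errors are drawn once per
    molecule and therefore shared by all its UMIs (they never create
    discordant pools); deamination follows the LA template model.
    """
    if arm not in ("meth", "unmeth"):
        raise ValueError(f"unknown arm {arm!r}")
    rng = config.rng(6, 0 if arm == "meth" else 1)
    methylated = arm == "meth"
    reads, manifest = [], []
    for m in range(config.n_barcodes):
        molecule = (
            random_dna(rng, OLIGO_FLANK) + OLIGO_CORE + random_dna(rng, OLIGO_FLANK)
        )
        synthesized = inject_substitutions(rng, molecule, config.synthesis_error)
        # Deamination schedule on the synthesized template.
        schedule: dict[int, int] = {}
        for i, base in enumerate(synthesized):
            if base != "C":
                continue
            in_cpg = i + 1 < len(synthesized) and synthesized[i + 1] == "G"
            rate = (
                config.deamination_meth
                if (methylated and in_cpg and i == OLIGO_CPG_C)
                else config.deamination_unmeth
            )
            if rate <= 0:
                continue
            t = int(rng.geometric(rate))
            if t <= config.la_cycles:
                schedule[i] = t
        n_umis = max(1, int(rng.poisson(config.umis_per_barcode)))
        for u in range(n_umis):
            umi = random_dna(rng, UMI_LENGTH)
            cycle = int(rng.integers(1, config.la_cycles + 1))
            copy = _apply_deamination(synthesized, 0, schedule, cycle)
            copy = inject_substitutions(rng, copy, config.polymerase_error)
            n_reads = int(rng.geometric(1.0 / config.reads_per_umi))
            for r in range(n_reads):
                name = f"oligo:{arm}:{m}:{u}:{r}"
                reads.append(
                    (name, umi + inject_substitutions(rng, copy, config.sequencing_error))
                )
        manifest.append(
            {
                "molecule": m,
                "barcode": molecule[:OLIGO_FLANK] + molecule[-OLIGO_FLANK:],
                "methylated": methylated,
                "synthesis_errors": synthesized != molecule,
                "deaminated": bool(schedule),
            }
        )
    return reads, pd.DataFrame(manifest)


def simulate_barcode_panel(config: SimConfig) -> pd.DataFrame:
    """A bare panel of unique barcodes, for studies that skip the genome.

    Quantification-only experiments (bias recovery, LA/PCR discordance) need
    repair outcomes and amplicon reads but no insertion loci; this returns a
    frame usable by :func:`simulate_repair_outcomes`.
    """
    rng = config.rng(9)
    barcodes: set[str] = set()
    while len(barcodes) < config.n_barcodes:
        barcodes.add(random_dna(rng, BARCODE_LENGTH))
    return pd.DataFrame({"barcode": sorted(barcodes)})


# -- direct outcome draws (replicate-concordance studies) ---------------------


def simulate_replicate_outcomes(
    n_barcodes: int,
    p_top: float,
    clonal: bool,
    n_replicates: int = 2,
    seed: int = 1,
) -> dict[str, dict[str, str]]:
    """Per-barcode outcomes across replicates, clonal or independent.

    Clonal barcodes carry one fixed outcome replicated identically (the
    pre-recombined situation); otherwise each replicate redraws the outcome
    independently with P(top) = ``p_top``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    outcomes: dict[str, dict[str, str]] = {}
    for i in range(n_barcodes):
        if clonal:
            call = "top" if rng.random() < p_top else "bottom"
            outcomes[f"bc{i}"] = {f"rep{r}": call for r in range(n_replicates)}
        else:
            outcomes[f"bc{i}"] = {
                f"rep{r}": "top" if rng.random() < p_top else "bottom"
                for r in range(n_replicates)
            }
    return outcomes


# -- training records for the context model -----------------------------------


def simulate_training_records(
    n: int,
    task: str,
    signal: bool,
    seed: int = 1,
    n_tracks: int = 78,
) -> pd.DataFrame:
    """Synthetic records for the Beta-likelihood network.

    With ``signal=True`` the chromatin tracks are Bernoulli draws whose
    logits depend on a latent GC-like variable which is also the outcome, so
    the full model can learn while the bookkeeping-only null cannot.  With
    ``signal=False`` the outcome is drawn independently of all features.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 8)))
    construct = rng.integers(0, 5, size=n)
    book = pd.DataFrame(
        {
            **{f"construct_{k}": (construct == k + 1).astype(float) for k in range(4)},
            "timepoint": rng.integers(0, 2, size=n).astype(float),
            "technology": rng.integers(0, 2, size=n).astype(float),
            "pool": rng.integers(0, 2, size=n).astype(float),
        }
    )
    latent = rng.beta(4.0, 4.0, size=n) * 0.5 + 0.25  # GC-like, in (0.25, 0.75)
    coeffs = rng.normal(0.0, 3.0, size=n_tracks)
    offsets = rng.normal(-2.0, 0.5, size=n_tracks)
    if signal:
        logits = (latent[:, None] - 0.5) * coeffs[None, :] + offsets[None, :]
        tracks = (rng.random((n, n_tracks)) < 1.0 / (1.0 + np.exp(-logits))).astype(float)
        outcome = latent
    else:
        tracks = (rng.random((n, n_tracks)) < 0.05).astype(float)
        outcome = rng.beta(7.0, 3.0, size=n)  # matches a 70% bias, no context
    df = book
    for j in range(n_tracks):
        df[f"track_{j}"] = tracks[:, j]
    df["gc_10kb"] = latent if signal else rng.beta(4.0, 4.0, size=n) * 0.5 + 0.25
    df["gc_1Mb"] = df["gc_10kb"] * 0.5 + 0.25
    df["outcome"] = np.clip(outcome, 1e-3, 1 - 1e-3)
    if task == "gc":
        df["outcome"] = np.clip(df["gc_10kb"], 1e-3, 1 - 1e-3)
    return df
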