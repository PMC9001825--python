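"""CpG methylation inference from deamination-induced C>T discordance.

During 50-cycle linear amplification, a template cytosine that spontaneously
deaminates at cycle t turns into thymine (or uracil) in every copy made from
cycle t onward, producing a barcode whose UMI pool contains both the
reference base and the C>T variant — the "smoking gun" of deamination.
Synthesis errors, in contrast, are present on the template from the start
and are shared by every UMI, so they never produce discordant pools.
Methylated cytosines deaminate roughly an order of magnitude faster, so the
ratio of C>T discordance inside vs outside CpGs is a methylation signature:
around 10 for methylated CpGs, much lower otherwise.

Calibration uses control oligonucleotides (GATCGATC flanked by two 12-nt
random arms forming a split barcode) with the central CpG either methylated
or not; the same logic applied to the 19 CpGs of the reporter's repeat
segment infers the methylation state of integrated reporters.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from tripssa.construct import (
    F_SEGMENT,
    F_SEGMENT_CPGS,
    MISMATCH_OFFSET,
    ReporterConstruct,
)
from tripssa.mapping import cluster_sequences, find_approximate
from tripssa.simulate import (
    FWD_CORE_START,
    OLIGO_CORE,
    OLIGO_FLANK,
    REV_CORE_END,
    UMI_LENGTH,
)
from tripssa.construct import revcomp

#: In-CpG positions of the oligo core GATCGATC (index of the C).
OLIGO_CPG_POSITIONS = frozenset(
    i for i in range(len(OLIGO_CORE) - 1) if OLIGO_CORE[i : i + 2] == "CG"
)

# Methylation classification thresholds on the in/out CpG C>T ratio,
# between the observed 2-4x (unmethylated) and ~10x (methylated) regimes.
METHYLATED_RATIO = 6.0
UNMETHYLATED_RATIO = 4.0


def umi_consensus(reads: list[str]) -> str | None:
    """Per-position majority consensus of one UMI's reads.

    UMIs with fewer than two reads are excluded (return None); reads whose
    length differs from the majority length are dropped; positional ties
    yield 'N', which never contributes evidence.
    """
    if len(reads) < 2:
        return None
    lengths = Counter(len(r) for r in reads)
    target_len = min(sorted(lengths, key=lambda L: (-lengths[L], L))[:1])
    kept = [r for r in reads if len(r) == target_len]
    if len(kept) < 2:
        return None
    consensus = []
    for i in range(target_len):
        counts = Counter(r[i] for r in kept)
        ranked = counts.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            consensus.append("N")
        else:
            consensus.append(ranked[0][0])
    return "".join(consensus)


@dataclass(frozen=True)
class Alteration:
    position: int
    ref_base: str
    alt_base: str
    in_cpg: bool

    @property
    def label(self) -> str:
        return f"{self.ref_base}>{self.alt_base}"


def alteration_evidence(
    consensi: list[str],
    reference: str,
    cpg_positions: frozenset[int] | set[int],
) -> set[Alteration]:
    """Discordance evidence for one barcode's UMI consensi.

    An alteration is evidenced iff at least one UMI consensus equals the
    reference exactly and at least one consensus differs from it by exactly
    that single-base substitution.  Barcodes whose UMIs all share the same
    alteration (synthesis errors) therefore yield nothing.
    """
    has_reference = any(c == reference for c in consensi)
    if not has_reference:
        return set()
    evidence: set[Alteration] = set()
    for cons in consensi:
        if cons == reference or len(cons) != len(reference):
            continue
        diffs = [i for i in range(len(reference)) if cons[i] != reference[i]]
        if len(diffs) != 1:
            continue
        i = diffs[0]
        if cons[i] == "N":
            continue
        evidence.add(
            Alteration(i, reference[i], cons[i], i in cpg_positions)
        )
    return evidence


# -- calibration oligos --------------------------------------------------------


def process_oligo_reads(
    reads: list[tuple[str, str]], max_dist: int = 2
) -> dict[str, list[str]]:
    """Group oligo reads into per-barcode UMI consensi of the central 8-mer.

    Each read is ``UMI + flank12 + GATCGATC + flank12``.  The two random
    flanks form a split barcode, treated as one concatenated 24-mer for
    clustering.  Returns barcode -> list of 8-mer consensi (>=2-read UMIs).
    """
    core_lo = UMI_LENGTH + OLIGO_FLANK
    core_hi = core_lo + len(OLIGO_CORE)
    by_pair: dict[tuple[str, str], list[str]] = defaultdict(list)
    bc_counts: Counter = Counter()
    umi_counts: Counter = Counter()
    parsed = []
    for _, seq in reads:
        if len(seq) < core_hi + OLIGO_FLANK:
            continue
        umi = seq[:UMI_LENGTH]
        barcode = seq[UMI_LENGTH:core_lo] + seq[core_hi : core_hi + OLIGO_FLANK]
        parsed.append((barcode, umi, seq[core_lo:core_hi]))
        bc_counts[barcode] += 1
        umi_counts[umi] += 1
    if not parsed:
        return {}
    bc_canon = cluster_sequences(dict(bc_counts), max_dist)
    umi_canon = cluster_sequences(dict(umi_counts), max_dist)
    for barcode, umi, core in parsed:
        by_pair[(bc_canon[barcode], umi_canon[umi])].append(core)
    consensi: dict[str, list[str]] = defaultdict(list)
    for (barcode, _), cores in sorted(by_pair.items()):
        cons = umi_consensus(cores)
        if cons is not None:
            consensi[barcode].append(cons)
    return dict(consensi)


def alteration_frequencies(
    consensi_by_barcode: dict[str, list[str]],
    methylated_arm: bool,
    reference: str = OLIGO_CORE,
    cpg_positions: frozenset[int] = OLIGO_CPG_POSITIONS,
    min_barcodes: int = 100,
) -> pd.DataFrame:
    """Percentage of barcodes with evidence, per substitution type and class.

    Classes: in-CpG (methylated or unmethylated according to the arm) and
    out-of-CpG.  Only barcodes with at least two UMI consensi can show
    discordance; all barcodes enter the denominator.
    """
    n = len(consensi_by_barcode)
    if n < min_barcodes:
        raise ValueError(f"need at least {min_barcodes} barcodes, got {n}")
    counts: Counter = Counter()
    for consensi in consensi_by_barcode.values():
        for alt in alteration_evidence(consensi, reference, cpg_positions):
            cls = (
                ("in_cpg_meth" if methylated_arm else "in_cpg_unmeth")
                if alt.in_cpg
                else "out_cpg"
            )
            counts[(alt.label, cls)] += 1
    rows = [
        {
            "alteration": label,
            "context": cls,
            "n_barcodes": n,
            "percent": 100.0 * k / n,
        }
        for (label, cls), k in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["alteration", "context", "n_barcodes", "percent"])


# -- reporter F segments -------------------------------------------------------

#: Out-of-CpG cytosines of the repeat segment (excluding the variant region).
F_SEGMENT_NONCPG_CS = tuple(
    i
    for i in range(len(F_SEGMENT))
    if F_SEGMENT[i] == "C"
    and i not in F_SEGMENT_CPGS
    and abs(i - MISMATCH_OFFSET) > 1
)


def reporter_reference(construct: ReporterConstruct) -> str:
    """Expected stitched consensus of an uncut reporter's two read windows.

    The reverse read covers the left repeat up to position 79 (including the
    top-strand allele), the forward read the right repeat from position 73;
    stitching takes the reverse window first.
    """
    return construct.left_repeat[:REV_CORE_END] + construct.f_segment[REV_CORE_END:]


def process_reporter_reads(
    read_pairs,
    construct: ReporterConstruct,
    max_dist: int = 2,
) -> dict[str, list[str]]:
    """Stitched per-UMI F-segment consensi for each reporter barcode."""
    by_pair: dict[tuple[str, str], list[tuple[str, str]]] = defaultdict(list)
    bc_counts: Counter = Counter()
    umi_counts: Counter = Counter()
    parsed = []
    fwd_core_len = len(construct.f_segment) - FWD_CORE_START
    for fwd, rev in read_pairs:
        hit = find_approximate(construct.watermark, fwd, 3)
        if hit is None or len(rev) <= UMI_LENGTH:
            continue
        barcode = fwd[: hit[0]]
        fwd_core = fwd[hit[1] : hit[1] + fwd_core_len]
        umi = rev[:UMI_LENGTH]
        rev_core = revcomp(rev[UMI_LENGTH : UMI_LENGTH + REV_CORE_END])
        if len(fwd_core) != fwd_core_len or len(rev_core) != REV_CORE_END:
            continue
        parsed.append((barcode, umi, fwd_core, rev_core))
        bc_counts[barcode] += 1
        umi_counts[umi] += 1
    if not parsed:
        return {}
    bc_canon = cluster_sequences(dict(bc_counts), max_dist)
    umi_canon = cluster_sequences(dict(umi_counts), max_dist)
    for barcode, umi, fwd_core, rev_core in parsed:
        by_pair[(bc_canon[barcode], umi_canon[umi])].append((fwd_core, rev_core))
    consensi: dict[str, list[str]] = defaultdict(list)
    for (barcode, _), cores in sorted(by_pair.items()):
        fwd_cons = umi_consensus([f for f, _ in cores])
        rev_cons = umi_consensus([r for _, r in cores])
        if fwd_cons is None or rev_cons is None:
            continue
        # Positions 0..78 from the reverse window, 79..151 from the forward.
        stitched = rev_cons + fwd_cons[REV_CORE_END - FWD_CORE_START :]
        consensi[barcode].append(stitched)
    return dict(consensi)


def cpg_ratio(
    consensi_by_barcode: dict[str, list[str]],
    construct: ReporterConstruct,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> dict:
    """Per-cytosine C>T rate ratio, inside vs outside the 19 CpGs.

    Uses uncut/control reporters only.  Frequencies are normalized per
    assayable cytosine so the ratio estimates the deamination rate ratio;
    the bootstrap resamples barcodes.
    """
    if not consensi_by_barcode:
        raise ValueError("no reporter barcodes")
    reference = reporter_reference(construct)
    cpg = frozenset(F_SEGMENT_CPGS)
    barcodes = sorted(consensi_by_barcode)
    in_events = np.zeros(len(barcodes))
    out_events = np.zeros(len(barcodes))
    for k, barcode in enumerate(barcodes):
        for alt in alteration_evidence(consensi_by_barcode[barcode], reference, cpg):
            if alt.label != "C>T":
                continue
            if alt.in_cpg:
                in_events[k] += 1
            elif alt.position in F_SEGMENT_NONCPG_CS:
                out_events[k] += 1
    n_in_sites = len(F_SEGMENT_CPGS)
    n_out_sites = len(F_SEGMENT_NONCPG_CS)

    def ratio(idx) -> float:
        p_in = in_events[idx].sum() / (len(idx) * n_in_sites)
        p_out = out_events[idx].sum() / (len(idx) * n_out_sites)
        return p_in / p_out if p_out > 0 else float("nan")

    all_idx = np.arange(len(barcodes))
    point = ratio(all_idx)
    if out_events.sum() == 0:
        return {"ratio": float("nan"), "ci_low": float("nan"), "ci_high": float("nan"),
                "n_barcodes": len(barcodes), "defined": False}
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    boots = [
        ratio(rng.integers(0, len(barcodes), size=len(barcodes)))
        for _ in range(n_bootstrap)
    ]
    boots = [b for b in boots if np.isfinite(b)]
    return {
        "ratio": float(point),
        "ci_low": float(np.percentile(boots, 2.5)) if boots else float("nan"),
        "ci_high": float(np.percentile(boots, 97.5)) if boots else float("nan"),
        "n_barcodes": len(barcodes),
        "defined": True,
    }


def classify_methylation(ratio: float) -> str:
    """Methylated-like (>=6), unmethylated-like (<=4), or indeterminate."""
    if not np.isfinite(ratio):
        return "indeterminate"
    if ratio >= METHYLATED_RATIO:
        return "methylated"
    if ratio <= UNMETHYLATED_RATIO:
        return "unmethylated"
    return "indeterminate"


def context_methylation_test(
    evidence_by_barcode: dict[str, bool],
    lookup: pd.DataFrame,
    features: pd.DataFrame,
    window_size: int = 200,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-mark proportion of reporters with a CG>TG transition, with tests.

    For every chromatin track: the proportion of mapped reporters in marked
    windows that show at least one in-CpG C>T discordance, a 99%
    normal-approximation confidence interval, and a two-tailed one-sample
    proportion test against the global mean.  Empty categories are omitted.
    """
    mapped = lookup[lookup["status"] == "unique"][["barcode", "chrom", "pos"]].copy()
    mapped["evidence"] = [
        evidence_by_barcode.get(b, False) for b in mapped["barcode"]
    ]
    mapped = mapped[mapped["barcode"].isin(evidence_by_barcode)]
    if mapped.empty:
        raise ValueError("no mapped reporters with methylation data")
    mapped["window_start"] = (mapped["pos"] // window_size) * window_size
    df = mapped.merge(
        features, left_on=["chrom", "window_start"], right_on=["chrom", "start"]
    )
    global_p = df["evidence"].mean()
    rows = []
    for col in [c for c in features.columns if c.startswith("track_")]:
        sub = df[df[col] == 1]
        if len(sub) == 0:
            continue
        k, n = int(sub["evidence"].sum()), len(sub)
        low, high = proportion_confint(k, n, alpha=0.01, method="normal")
        if 0 < k < n:
            _, p_value = proportions_ztest(k, n, value=global_p)
        else:
            p_value = 1.0 if np.isclose(k / n, global_p) else 0.0
        rows.append(
            {
                "track": col,
                "n": n,
                "proportion": k / n,
                "ci_low": float(low),
                "ci_high": float(high),
                "global_proportion": global_p,
                "p": float(p_value),
                "significant": p_value < alpha,
            }
        )
    return pd.DataFrame(rows)


def reporter_evidence_flags(
    consensi_by_barcode: dict[str, list[str]], construct: ReporterConstruct
) -> dict[str, bool]:
    """Whether each reporter barcode shows >=1 in-CpG C>T discordance."""
    reference = reporter_reference(construct)
    cpg = frozenset(F_SEGMENT_CPGS)
    return {
        barcode: any(
            alt.label == "C>T" and alt.in_cpg
            for alt in alteration_evidence(consensi, reference, cpg)
        )
        for barcode, consensi in consensi_by_barcode.items()
    }
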