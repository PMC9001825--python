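"""Repair-outcome calling from UMI-amplicon reads and strand-bias estimation.

The forward amplicon read carries ``barcode + watermark`` followed by the
right half of the distal repeat (3 nt past the segment midpoint); the
reverse read carries the 18-nt UMI followed by the left half of the proximal
repeat (also 3 nt past the midpoint).  After SSA only one repeat remains, so
the two reads cover the same molecule and the nucleotides they report at the
variant position are reverse complements of each other; this complementarity
is the SSA signature.  Uncut or NHEJ-repaired reporters keep two repeats and
the reads report the two distinct alleles instead.

Votes are counted per UMI, not per read: barcode-UMI pairs with a single
read are discarded, UMIs seen with more than one barcode are discarded as
template-switching chimeras, and barcodes are filtered (more NHEJ than SSA
votes, single UMI, or present in the no-induction control) before the
global bias is estimated as the proportion of remaining UMIs reporting the
top-strand allele.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from tripssa.construct import (
    MISMATCH_OFFSET,
    ReporterConstruct,
    complement,
    revcomp,
)
from tripssa.mapping import cluster_sequences, find_approximate
from tripssa.simulate import FWD_CORE_START, REV_CORE_END, UMI_LENGTH

MAX_HALF_SEGMENT_ERRORS = 10
WATERMARK_ERRORS = 3


@dataclass
class AmpliconCall:
    barcode: str | None
    umi: str | None
    call: str | None  # top | bottom | NHEJ
    reject_reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.reject_reason is None


@dataclass
class UmiVote:
    barcode: str
    umi: str
    read_count: int
    call: str  # top | bottom | NHEJ


@dataclass
class BarcodeRepairCall:
    barcode: str
    replicate: int
    n_top: int
    n_bottom: int
    n_nhej: int
    retained: bool
    filter_reason: str | None
    majority_allele: str | None
    has_conflict: bool

    @property
    def n_umis(self) -> int:
        return self.n_top + self.n_bottom + self.n_nhej


@dataclass
class BiasEstimate:
    construct: str
    replicate: int | None
    n_umis: int
    n_barcodes: int
    bias: float
    ci_low: float
    ci_high: float


def _aligned_base(reference: str, query: str, ref_offset: int) -> tuple[str, int] | None:
    """Base of ``query`` aligned to ``reference[ref_offset]`` (infix alignment).

    Walks the alignment path so that indels upstream of the variant do not
    shift the readout.  Returns (base, edit_distance) or None when the
    reference cannot be found within the error budget.
    """
    res = edlib.align(
        reference, query, mode="HW", task="path", k=MAX_HALF_SEGMENT_ERRORS
    )
    if res["editDistance"] < 0:
        return None
    start = min(res["locations"], key=lambda loc: (loc[1], loc[0]))[0]
    qpos, rpos = start, 0
    cigar = res["cigar"]
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=XM":
            if rpos + n > ref_offset:
                qpos += ref_offset - rpos
                return (
                    (query[qpos], res["editDistance"])
                    if qpos < len(query)
                    else None
                )
            rpos += n
            qpos += n
        elif ch == "I":  # insertion in target = consumes reference
            if rpos + n > ref_offset:
                return None  # the variant base is deleted in the read
            rpos += n
        elif ch == "D":
            qpos += n
    return None


def parse_amplicon_pair(
    fwd: str, rev: str, construct: ReporterConstruct
) -> AmpliconCall:
    """Classify one read pair as SSA (with allele), NHEJ, or reject."""
    hit = find_approximate(construct.watermark, fwd, WATERMARK_ERRORS)
    if hit is None:
        return AmpliconCall(None, None, None, "no_watermark")
    barcode = fwd[: hit[0]]
    if not barcode:
        return AmpliconCall(None, None, None, "no_barcode")
    fwd_rest = fwd[hit[1] :]
    if len(rev) <= UMI_LENGTH:
        return AmpliconCall(barcode, None, None, "short_reverse")
    umi = rev[:UMI_LENGTH]
    rev_rest = revcomp(rev[UMI_LENGTH:])

    ref_fwd = construct.f_segment[FWD_CORE_START:]
    ref_rev = construct.f_segment[:REV_CORE_END]
    fwd_hit = _aligned_base(ref_fwd, fwd_rest, MISMATCH_OFFSET - FWD_CORE_START)
    rev_hit = _aligned_base(ref_rev, rev_rest, MISMATCH_OFFSET)
    if fwd_hit is None or rev_hit is None:
        return AmpliconCall(barcode, umi, None, "missing_half_segment")
    a, c = fwd_hit[0], rev_hit[0]

    mm = construct.mismatch
    if a == c:
        # Both reads report the same top-strand base: one repeat, i.e. SSA;
        # the raw reverse read carries its complement.
        if a == mm.top_allele:
            return AmpliconCall(barcode, umi, "top")
        if a == complement(mm.bottom_allele):
            return AmpliconCall(barcode, umi, "bottom")
        return AmpliconCall(barcode, umi, None, "allele_mismatch")
    if a == complement(mm.bottom_allele) and c == mm.top_allele:
        return AmpliconCall(barcode, umi, "NHEJ")
    return AmpliconCall(barcode, umi, None, "discordant_pair")


def tabulate_umis(records: list[AmpliconCall], max_dist: int = 2) -> list[UmiVote]:
    """Cluster-correct barcodes and UMIs, vote per pair, drop unreliable UMIs.

    Pairs with a single read are discarded; read-level ties reject the UMI;
    UMIs associated with more than one barcode afterwards are discarded as
    template-switching chimeras.
    """
    accepted = [r for r in records if r.accepted]
    if not accepted:
        return []
    bc_canon = cluster_sequences(Counter(r.barcode for r in accepted), max_dist)
    umi_canon = cluster_sequences(Counter(r.umi for r in accepted), max_dist)

    pair_calls: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for r in accepted:
        pair_calls[(bc_canon[r.barcode], umi_canon[r.umi])][r.call] += 1

    votes: list[UmiVote] = []
    umi_barcodes: dict[str, set] = defaultdict(set)
    for (barcode, umi), calls in sorted(pair_calls.items()):
        n_reads = sum(calls.values())
        if n_reads < 2:
            continue
        top_calls = calls.most_common()
        if len(top_calls) > 1 and top_calls[0][1] == top_calls[1][1]:
            continue  # read-level tie: reject the UMI (conservative)
        votes.append(UmiVote(barcode, umi, n_reads, top_calls[0][0]))
        umi_barcodes[umi].add(barcode)

    return [v for v in votes if len(umi_barcodes[v.umi]) == 1]


def call_barcodes(
    votes: list[UmiVote],
    control_barcode_set: set[str] | frozenset[str] = frozenset(),
    replicate: int = 0,
) -> list[BarcodeRepairCall]:
    """Apply the published barcode filters in order and call the majority allele.

    Filters: (1) strictly more NHEJ than SSA votes; (2) a single UMI;
    (3) presence in the no-induction control set (matched by clustered
    barcode sequence).
    """
    by_barcode: dict[str, list[UmiVote]] = defaultdict(list)
    for v in votes:
        by_barcode[v.barcode].append(v)

    calls = []
    for barcode, bc_votes in sorted(by_barcode.items()):
        n_top = sum(1 for v in bc_votes if v.call == "top")
        n_bottom = sum(1 for v in bc_votes if v.call == "bottom")
        n_nhej = sum(1 for v in bc_votes if v.call == "NHEJ")
        n_ssa = n_top + n_bottom
        reason = None
        if n_nhej > n_ssa:
            reason = "more_nhej_than_ssa"
        elif n_top + n_bottom + n_nhej < 2:
            reason = "single_umi"
        elif barcode in control_barcode_set:
            reason = "in_control"
        majority = None
        if n_top > n_bottom:
            majority = "top"
        elif n_bottom > n_top:
            majority = "bottom"
        calls.append(
            BarcodeRepairCall(
                barcode=barcode,
                replicate=replicate,
                n_top=n_top,
                n_bottom=n_bottom,
                n_nhej=n_nhej,
                retained=reason is None,
                filter_reason=reason,
                majority_allele=majority,
                has_conflict=n_top > 0 and n_bottom > 0,
            )
        )
    return calls


def global_bias(
    calls: list[BarcodeRepairCall],
    construct: str = "",
    replicate: int | None = None,
) -> BiasEstimate:
    """Pooled proportion of retained UMIs reporting the top-strand allele."""
    retained = [c for c in calls if c.retained]
    if not retained:
        raise ValueError("no retained barcode")
    n_top = sum(c.n_top for c in retained)
    n_all = n_top + sum(c.n_bottom for c in retained)
    if n_all == 0:
        raise ValueError("zero retained allele-reporting UMIs")
    low, high = proportion_confint(n_top, n_all, alpha=0.05, method="wilson")
    return BiasEstimate(
        construct=construct,
        replicate=replicate,
        n_umis=n_all,
        n_barcodes=len(retained),
        bias=n_top / n_all,
        ci_low=float(low),
        ci_high=float(high),
    )


def conflict_rate(calls: list[BarcodeRepairCall]) -> float:
    """Proportion of retained barcodes with at least one dissenting UMI."""
    retained = [c for c in calls if c.retained and (c.n_top + c.n_bottom) > 0]
    if not retained:
        raise ValueError("no retained barcode with allele votes")
    return sum(c.has_conflict for c in retained) / len(retained)


def swap_strand_labels(votes: list[UmiVote]) -> list[UmiVote]:
    """Relabel strands: top <-> bottom.  Biases map b -> 1 - b exactly."""
    flip = {"top": "bottom", "bottom": "top", "NHEJ": "NHEJ"}
    return [UmiVote(v.barcode, v.umi, v.read_count, flip[v.call]) for v in votes]


def calls_to_frame(calls: list[BarcodeRepairCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "barcode": c.barcode,
                "replicate": c.replicate,
                "n_top": c.n_top,
                "n_bottom": c.n_bottom,
                "n_nhej": c.n_nhej,
                "retained": c.retained,
                "filter_reason": c.filter_reason,
                "majority_allele": c.majority_allele,
                "has_conflict": c.has_conflict,
            }
            for c in calls
        ]
    )


def run_quantification(
    read_pairs,
    construct: ReporterConstruct,
    control_barcode_set: set[str] | frozenset[str] = frozenset(),
    replicate: int = 0,
) -> tuple[list[BarcodeRepairCall], list[UmiVote], Counter]:
    """Parse, tabulate and call one replicate run."""
    rejects: Counter = Counter()
    records = []
    for fwd, rev in read_pairs:
        rec = parse_amplicon_pair(fwd, rev, construct)
        records.append(rec)
        if not rec.accepted:
            rejects[rec.reject_reason] += 1
    votes = tabulate_umis(records)
    calls = call_barcodes(votes, control_barcode_set, replicate)
    return calls, votes, rejects


def bias_by_context(
    calls: pd.DataFrame,
    lookup: pd.DataFrame,
    features: pd.DataFrame,
    window_size: int = 200,
    annotation: pd.DataFrame | None = None,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bias per genomic category and per chromatin track, with coefficient tests.

    ``calls`` is the per-barcode, per-replicate frame (columns n_top,
    n_bottom, retained); only retained, uniquely mapped barcodes enter.  For
    every track, the per-record bias fraction is regressed on track presence
    with replicate fixed effects and the track coefficient is t-tested.
    """
    import statsmodels.api as sm

    mapped = lookup[lookup["status"] == "unique"][["barcode", "chrom", "pos"]]
    df = calls[calls["retained"] & ((calls["n_top"] + calls["n_bottom"]) > 0)].merge(
        mapped, on="barcode", how="inner"
    )
    if df.empty:
        raise ValueError("no mapped retained barcodes")
    df["window_start"] = (df["pos"] // window_size) * window_size
    df = df.merge(
        features, left_on=["chrom", "window_start"], right_on=["chrom", "start"]
    )
    df["bias"] = df["n_top"] / (df["n_top"] + df["n_bottom"])

    cat_rows = []
    if annotation is not None:
        ann = annotation.sort_values(["chrom", "start"])
        cats = []
        for row in df.itertuples():
            grp = ann[ann["chrom"] == row.chrom]
            hit = grp[(grp["start"] <= row.pos) & (row.pos < grp["end"])]
            cats.append(hit.iloc[0]["category"] if len(hit) else "intergenic")
        df["category"] = cats
        for category, grp in df.groupby("category"):
            n_top, n_all = grp["n_top"].sum(), (grp["n_top"] + grp["n_bottom"]).sum()
            low, high = proportion_confint(n_top, n_all, alpha=0.05, method="wilson")
            cat_rows.append(
                {
                    "category": category,
                    "n_barcodes": len(grp),
                    "bias": n_top / n_all,
                    "ci_low": float(low),
                    "ci_high": float(high),
                }
            )
    per_category = pd.DataFrame(cat_rows)

    track_cols = [c for c in features.columns if c.startswith("track_")]
    rep_dummies = pd.get_dummies(df["replicate"], prefix="rep", drop_first=True)
    track_rows = []
    for col in track_cols:
        if df[col].nunique() < 2:
            continue  # track absent (or ubiquitous) among mapped barcodes
        X = pd.concat(
            [pd.Series(1.0, index=df.index, name="const"), df[col], rep_dummies],
            axis=1,
        ).astype(float)
        fit = sm.OLS(df["bias"].astype(float), X).fit()
        track_rows.append(
            {
                "track": col,
                "coef": fit.params[col],
                "t": fit.tvalues[col],
                "p": fit.pvalues[col],
                "significant": fit.pvalues[col] < alpha,
                "n_with_track": int(df[col].sum()),
            }
        )
    per_track = pd.DataFrame(track_rows)
    return per_category, per_track
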