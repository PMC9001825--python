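"""Barcode-to-locus lookup table from inverse-PCR reads.

The forward iPCR read carries ``barcode + watermark + CATG + genomic flank``;
the reverse read carries a 25-nt vector stub followed by the genomic sequence
at the insertion site, truncated at the next NlaIII site (CATG) when one is
present.  Parsing locates the 20-nt watermark by approximate matching (up to
3 edits), takes the prefix as the barcode, and keeps the reverse-read
fragment when it is at least 20 nt.  Barcodes are error-corrected by greedy
abundance clustering (edit distance <= 2), fragments are placed on the
genome by exact unique substring search on both strands, and each barcode is
assigned a unique locus when its candidate sites are concentrated within a
30-nt diameter.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from tripssa.construct import WATERMARK, revcomp

VECTOR_STUB_LENGTH = 25
NLAIII = "CATG"
MIN_BARCODE, MAX_BARCODE = 14, 24
MIN_FRAGMENT = 20
MAX_DIAMETER = 30  # "greater than 30" discards, so 30 itself is kept


def find_approximate(
    pattern: str, read: str, max_errors: int
) -> tuple[int, int, int] | None:
    """Best approximate occurrence of ``pattern`` in ``read``.

    Returns ``(start, end, distance)`` for the minimum-edit-distance span
    (substitutions and indels), choosing the leftmost span on ties, or None
    if no span has distance <= ``max_errors``.  ``end`` is exclusive.
    """
    if not pattern:
        raise ValueError("empty pattern")
    res = edlib.align(pattern, read, mode="HW", task="locations", k=max_errors)
    if res["editDistance"] < 0:
        return None
    start, end = min(res["locations"], key=lambda loc: (loc[1], loc[0]))
    return start, end + 1, res["editDistance"]


@dataclass
class IpcrRecord:
    barcode: str | None
    genomic_fragment: str | None
    reject_reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.reject_reason is None


def parse_ipcr_pair(
    fwd: str, rev: str, watermark: str = WATERMARK, max_errors: int = 3
) -> IpcrRecord:
    """Extract barcode and genomic fragment from one iPCR read pair."""
    if not fwd or not rev:
        raise ValueError("empty read in pair")
    hit = find_approximate(watermark, fwd, max_errors)
    if hit is None:
        return IpcrRecord(None, None, "no_watermark")
    barcode = fwd[: hit[0]]
    if not (MIN_BARCODE <= len(barcode) <= MAX_BARCODE):
        return IpcrRecord(None, None, "barcode_length")
    fragment = rev[VECTOR_STUB_LENGTH:]
    cut = fragment.find(NLAIII)
    if cut >= 0:
        fragment = fragment[:cut]
    if len(fragment) < MIN_FRAGMENT:
        return IpcrRecord(barcode, None, "short_fragment")
    return IpcrRecord(barcode, fragment)


def _chunks(seq: str) -> list[tuple[int, str]]:
    # Pigeonhole blocking: a <=2-substitution neighbour of equal length
    # shares at least one of three chunks exactly.
    n = len(seq)
    a, b = n // 3, 2 * n // 3
    return [(0, seq[:a]), (1, seq[a:b]), (2, seq[b:])]


def cluster_sequences(
    counts: dict[str, int], max_dist: int = 2
) -> dict[str, str]:
    """Greedy abundance clustering: map each sequence to a canonical.

    Sequences are visited in order of descending read count (ties broken
    lexicographically).  A sequence joins the most abundant existing
    canonical within edit distance ``max_dist``, otherwise it becomes a
    canonical itself.  Candidate canonicals are retrieved through exact
    chunk matches, so the scheme is exhaustive for substitution errors and
    approximate for indels.
    """
    if not counts:
        raise ValueError("empty count table")
    order = sorted(counts, key=lambda s: (-counts[s], s))
    rank = {s: i for i, s in enumerate(order)}
    assignment: dict[str, str] = {}
    chunk_index: dict[tuple[int, str], list[str]] = defaultdict(list)
    for seq in order:
        candidates: set[str] = set()
        for key in _chunks(seq):
            candidates.update(chunk_index[key])
        best = None
        for cand in sorted(candidates, key=rank.__getitem__):
            d = edlib.align(seq, cand, mode="NW", task="distance", k=max_dist)[
                "editDistance"
            ]
            if 0 <= d <= max_dist:
                best = cand
                break
        if best is None:
            assignment[seq] = seq
            for key in _chunks(seq):
                chunk_index[key].append(seq)
        else:
            assignment[seq] = best
    return assignment


@dataclass
class BarcodeLocus:
    barcode: str
    chromosome: str | None
    position: int | None
    strand: str | None
    status: str  # unique | multi | discarded
    site_read_counts: dict


def assign_locus(
    barcode: str,
    site_read_counts: dict[tuple[str, int, str], int],
    mapping_flags: dict[tuple[str, int, str], bool],
    min_site_fraction: float = 0.10,
) -> BarcodeLocus:
    """Assign one barcode to a unique genomic position, or discard it.

    Candidate sites are those totalling at least ``min_site_fraction`` of
    the barcode's reads.  The diameter is the maximum pairwise distance
    between candidate positions, infinite across chromosomes or when a
    candidate is flagged multi-mapping; barcodes whose diameter exceeds 30
    are discarded.  The retained position is the most frequent candidate
    (lowest coordinate on ties).
    """
    if not site_read_counts:
        raise ValueError(f"no mapped reads for barcode {barcode}")
    total = sum(site_read_counts.values())
    candidates = {
        site: n
        for site, n in site_read_counts.items()
        if n >= min_site_fraction * total
    }
    if any(mapping_flags.get(site, False) for site in candidates):
        return BarcodeLocus(barcode, None, None, None, "multi", site_read_counts)
    chroms = {site[0] for site in candidates}
    if len(chroms) > 1:
        return BarcodeLocus(barcode, None, None, None, "discarded", site_read_counts)
    positions = [site[1] for site in candidates]
    diameter = max(positions) - min(positions)
    if diameter > MAX_DIAMETER:
        return BarcodeLocus(barcode, None, None, None, "discarded", site_read_counts)
    site = min(candidates, key=lambda s: (-candidates[s], s[1]))
    return BarcodeLocus(barcode, site[0], site[1], site[2], "unique", site_read_counts)


class ToyAligner:
    """Exact unique substring search over a small controlled genome.

    Fragments are searched on both strands; more than one occurrence flags
    the fragment as multi-mapping.  Positions refer to the top strand start
    of the fragment.
    """

    def __init__(self, genome: dict[str, str]):
        self.genome = genome

    def map_fragment(self, fragment: str) -> list[tuple[str, int, str]]:
        hits: list[tuple[str, int, str]] = []
        rc = revcomp(fragment)
        for chrom, seq in self.genome.items():
            for query, strand in ((fragment, "+"), (rc, "-")):
                start = seq.find(query)
                while start >= 0:
                    hits.append((chrom, start, strand))
                    if len(hits) > 1:
                        return hits
                    start = seq.find(query, start + 1)
        return hits


def build_lookup(
    read_pairs,
    genome: dict[str, str],
    watermark: str = WATERMARK,
) -> tuple[pd.DataFrame, Counter]:
    """Full mapping stage: parse, cluster, align, assign.

    ``read_pairs`` yields (fwd_sequence, rev_sequence) tuples.  Returns the
    lookup table (one row per clustered barcode) and a tally of reject
    reasons.
    """
    rejects: Counter = Counter()
    records: list[IpcrRecord] = []
    for fwd, rev in read_pairs:
        rec = parse_ipcr_pair(fwd, rev, watermark)
        if rec.accepted:
            records.append(rec)
        else:
            rejects[rec.reject_reason] += 1
    if not records:
        raise ValueError("no accepted iPCR records")

    barcode_counts = Counter(rec.barcode for rec in records)
    canon = cluster_sequences(dict(barcode_counts))

    aligner = ToyAligner(genome)
    fragment_hits: dict[str, list] = {}
    site_counts: dict[str, Counter] = defaultdict(Counter)
    multi_flags: dict[tuple[str, int, str], bool] = {}
    for rec in records:
        hits = fragment_hits.get(rec.genomic_fragment)
        if hits is None:
            hits = aligner.map_fragment(rec.genomic_fragment)
            fragment_hits[rec.genomic_fragment] = hits
        if not hits:
            rejects["unmapped_fragment"] += 1
            continue
        site = hits[0]
        multi = len(hits) > 1
        multi_flags[site] = multi_flags.get(site, False) or multi
        site_counts[canon[rec.barcode]][site] += 1

    rows = []
    for barcode, counts in sorted(site_counts.items()):
        locus = assign_locus(barcode, dict(counts), multi_flags)
        rows.append(
            {
                "barcode": locus.barcode,
                "chrom": locus.chromosome,
                "pos": locus.position,
                "strand": locus.strand,
                "status": locus.status,
                "reads": sum(counts.values()),
            }
        )
    lookup = pd.DataFrame(
        rows, columns=["barcode", "chrom", "pos", "strand", "status", "reads"]
    )
    return lookup, rejects


def insertion_enrichment(
    lookup: pd.DataFrame,
    annotation: pd.DataFrame,
    chrom_sizes: dict[str, int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed/expected insertion ratios per chromosome and per category.

    The expectation is the uniform model: insertions proportional to the
    number of base pairs.  ``annotation`` has columns chrom, start, end,
    category and must tile the genome.
    """
    mapped = lookup[lookup["status"] == "unique"]
    if mapped.empty:
        raise ValueError("no uniquely mapped insertions")
    n = len(mapped)
    genome_size = sum(chrom_sizes.values())

    chrom_rows = []
    for chrom, size in chrom_sizes.items():
        obs = int((mapped["chrom"] == chrom).sum())
        exp = n * size / genome_size
        chrom_rows.append(
            {"chrom": chrom, "observed": obs, "expected": exp, "obs_exp": obs / exp}
        )
    per_chrom = pd.DataFrame(chrom_rows)

    cat_obs: Counter = Counter()
    cat_bp: Counter = Counter()
    ann = annotation.sort_values(["chrom", "start"])
    for row in ann.itertuples():
        cat_bp[row.category] += row.end - row.start
    starts_by_chrom = {
        chrom: grp.reset_index(drop=True) for chrom, grp in ann.groupby("chrom")
    }
    for row in mapped.itertuples():
        grp = starts_by_chrom.get(row.chrom)
        if grp is None:
            continue
        idx = int(np.searchsorted(grp["start"].to_numpy(), row.pos, side="right")) - 1
        if idx >= 0 and row.pos < grp.loc[idx, "end"]:
            cat_obs[grp.loc[idx, "category"]] += 1
    cat_rows = []
    for category, bp in sorted(cat_bp.items()):
        exp = n * bp / genome_size
        obs = cat_obs[category]
        cat_rows.append(
            {
                "category": category,
                "observed": obs,
                "expected": exp,
                "obs_exp": obs / exp if exp else float("nan"),
            }
        )
    per_category = pd.DataFrame(cat_rows)
    return per_chrom, per_category
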