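import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tripssa.construct import WATERMARK
from tripssa.mapping import (
    BarcodeLocus,
    ToyAligner,
    assign_locus,
    build_lookup,
    cluster_sequences,
    find_approximate,
    insertion_enrichment,
    parse_ipcr_pair,
)
from tripssa.simulate import (
    SimConfig,
    random_dna,
    simulate_genome,
    simulate_insertions,
    simulate_ipcr_reads,
)

from conftest import as_pairs


def dp_best_match(pattern: str, read: str):
    """Brute-force semi-global alignment: minimal edit distance, leftmost end."""
    m, n = len(pattern), len(read)
    prev = [0] * (n + 1)  # free start in the read
    rows = [prev]
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if pattern[i - 1] == read[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    best = min(prev)
    end = prev.index(best)
    return best, end


class TestFindApproximate:
    def test_exact_match(self):
        read = "TT" + WATERMARK + "AAAA"
        assert find_approximate(WATERMARK, read, 3) == (2, 2 + len(WATERMARK), 0)

    def test_error_budget_boundary(self):
        mutated = "G" + WATERMARK[4:]  # 3-nt deletion plus a substitution: 4 edits
        assert find_approximate(mutated, "CC" + WATERMARK + "TT", 3) is not None
        four_edits = "GGGG" + WATERMARK[4:]
        hit = find_approximate(four_edits, "CC" + WATERMARK + "TT", 3)
        if hit is not None:
            assert hit[2] <= 3

    def test_three_substitutions_found_four_rejected(self):
        w = list(WATERMARK)
        for k, pos in enumerate((1, 6, 11)):
            w[pos] = "A" if WATERMARK[pos] != "A" else "C"
        read = "TTTT" + "".join(w) + "GGGG"
        hit = find_approximate(WATERMARK, read, 3)
        assert hit is not None and hit[2] == 3
        w[16] = "A" if WATERMARK[16] != "A" else "C"
        assert find_approximate(WATERMARK, "TTTT" + "".join(w) + "GGGG", 3) is None

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_agrees_with_dp_oracle(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        pattern = random_dna(rng, int(rng.integers(5, 15)))
        read = random_dna(rng, int(rng.integers(20, 60)))
        best, end = dp_best_match(pattern, read)
        hit = find_approximate(pattern, read, 3)
        if best > 3:
            assert hit is None
        else:
            assert hit is not None
            assert hit[2] == best
            assert hit[1] == end


class TestParseIpcr:
    def test_well_formed_pair(self):
        barcode = "ACGTACGTACGTACGTACGT"
        flank = "TTAACCGGTTAACCGGTTAACCGGTTAACC"
        fwd = barcode + WATERMARK + "CATG" + flank
        rev = "V" * 25 + flank
        rec = parse_ipcr_pair(fwd, rev)
        assert rec.accepted and rec.barcode == barcode
        assert rec.genomic_fragment == flank

    def test_barcode_length_rules(self):
        flank = "A" * 30
        rev = "V" * 25 + flank
        assert parse_ipcr_pair("C" * 13 + WATERMARK + flank, rev).reject_reason == "barcode_length"
        assert parse_ipcr_pair("C" * 14 + WATERMARK + flank, rev).accepted
        assert parse_ipcr_pair("C" * 24 + WATERMARK + flank, rev).accepted
        assert parse_ipcr_pair("C" * 25 + WATERMARK + flank, rev).reject_reason == "barcode_length"

    def test_no_watermark_rejected(self):
        assert parse_ipcr_pair("A" * 60, "V" * 25 + "A" * 30).reject_reason == "no_watermark"

    def test_fragment_truncated_at_catg_and_length_rule(self):
        fwd = "C" * 20 + WATERMARK + "CATG" + "A" * 30
        rev = "V" * 25 + "T" * 19 + "CATG" + "G" * 40
        assert parse_ipcr_pair(fwd, rev).reject_reason == "short_fragment"
        rev_ok = "V" * 25 + "T" * 20 + "CATG" + "G" * 40
        rec = parse_ipcr_pair(fwd, rev_ok)
        assert rec.accepted and rec.genomic_fragment == "T" * 20


class TestClustering:
    def test_error_absorption(self):
        big, small = "A" * 20, "A" * 19 + "T"
        canon = cluster_sequences({big: 100, small: 2})
        assert canon == {big: big, small: big}

    def test_distant_sequences_stay_apart(self):
        a, b = "A" * 20, "A" * 15 + "TTTTT"
        canon = cluster_sequences({a: 10, b: 9})
        assert canon[a] == a and canon[b] == b

    def test_deterministic_and_within_radius(self):
        rng = np.random.default_rng(5)
        counts = {}
        for _ in range(50):
            base = random_dna(rng, 20)
            counts[base] = int(rng.integers(10, 100))
            mutant = "T" + base[1:]
            counts.setdefault(mutant, 1)
        c1 = cluster_sequences(counts)
        c2 = cluster_sequences(dict(reversed(list(counts.items()))))
        assert c1 == c2
        import edlib

        for seq, canon in c1.items():
            d = edlib.align(seq, canon, mode="NW", task="distance")["editDistance"]
            assert d <= 2

    def test_recovers_true_barcode_count(self):
        # 1,000 true barcodes, reads with 1% per-base error: clustering
        # collapses the error halo back onto the truth.
        rng = np.random.default_rng(7)
        truth = {random_dna(rng, 20) for _ in range(1000)}
        counts = {}
        for barcode in truth:
            counts[barcode] = counts.get(barcode, 0) + 50
            for _ in range(3):
                seq = list(barcode)
                # Error halo within the clustering radius (<= 2 substitutions).
                for i in rng.choice(20, size=rng.integers(1, 3), replace=False):
                    seq[i] = "ACGT"[rng.integers(0, 4)]
                mutant = "".join(seq)
                if mutant not in truth:
                    counts[mutant] = counts.get(mutant, 0) + 1
        canon = cluster_sequences(counts)
        assert set(canon.values()) == truth


class TestAssignLocus:
    def test_nearby_sites_unique_at_modal(self):
        sites = {("chr1", 100, "+"): 60, ("chr1", 101, "+"): 40}
        locus = assign_locus("bc", sites, {})
        assert (locus.status, locus.chromosome, locus.position) == ("unique", "chr1", 100)

    def test_cross_chromosome_discarded(self):
        sites = {("chr1", 100, "+"): 55, ("chr2", 500, "+"): 45}
        assert assign_locus("bc", sites, {}).status == "discarded"

    def test_minor_site_below_threshold_ignored(self):
        sites = {("chr1", 100, "+"): 95, ("chr3", 900, "+"): 5}
        locus = assign_locus("bc", sites, {})
        assert (locus.status, locus.position) == ("unique", 100)

    def test_diameter_boundary_inclusive(self):
        near = {("chr1", 100, "+"): 50, ("chr1", 130, "+"): 50}
        far = {("chr1", 100, "+"): 50, ("chr1", 131, "+"): 50}
        assert assign_locus("bc", near, {}).status == "unique"
        assert assign_locus("bc", far, {}).status == "discarded"

    def test_multimapping_candidate_flags_barcode(self):
        sites = {("chr1", 100, "+"): 100}
        locus = assign_locus("bc", sites, {("chr1", 100, "+"): True})
        assert locus.status == "multi"

    def test_tie_breaks_to_lowest_coordinate(self):
        sites = {("chr1", 105, "+"): 50, ("chr1", 100, "+"): 50}
        assert assign_locus("bc", sites, {}).position == 100

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            assign_locus("bc", {}, {})


class TestToyAligner:
    def test_duplicated_segment_multimaps(self, genome_bundle):
        genome = genome_bundle["genome"]
        fragment = genome["chr1"][10_100:10_140]  # inside the duplicated block
        hits = ToyAligner(genome).map_fragment(fragment)
        assert len(hits) > 1

    def test_unique_fragment(self, genome_bundle):
        genome = genome_bundle["genome"]
        fragment = genome["chr3"][5_000:5_040]
        hits = ToyAligner(genome).map_fragment(fragment)
        assert hits == [("chr3", 5_000, "+")]


class TestLookupPipeline:
    def test_error_free_lookup_equals_truth(self, genome_bundle):
        config = SimConfig(seed=2, n_barcodes=150, sequencing_error=0.0)
        genome, annotation = simulate_genome(config)
        insertions = simulate_insertions(genome, annotation, config)
        fwd, rev = simulate_ipcr_reads(insertions, genome, config)
        lookup, rejects = build_lookup(as_pairs(fwd, rev), genome)
        truth = insertions.set_index("barcode")
        assert len(lookup) == len(insertions)
        assert (lookup["status"] == "unique").all()
        for row in lookup.itertuples():
            assert truth.loc[row.barcode, "chrom"] == row.chrom
            assert truth.loc[row.barcode, "pos"] == row.pos

    def test_read_order_invariance(self, genome_bundle):
        config = SimConfig(seed=2, n_barcodes=60, sequencing_error=0.0)
        genome, annotation = simulate_genome(config)
        insertions = simulate_insertions(genome, annotation, config)
        fwd, rev = simulate_ipcr_reads(insertions, genome, config)
        pairs = as_pairs(fwd, rev)
        lookup1, _ = build_lookup(pairs, genome)
        lookup2, _ = build_lookup(list(reversed(pairs)), genome)
        assert lookup1.sort_values("barcode").reset_index(drop=True).equals(
            lookup2.sort_values("barcode").reset_index(drop=True)
        )

    def test_truncated_barcodes_rejected(self):
        config = SimConfig(
            seed=3, n_barcodes=100, sequencing_error=0.0, ipcr_truncate_fraction=0.3
        )
        genome, annotation = simulate_genome(config)
        insertions = simulate_insertions(genome, annotation, config)
        fwd, rev = simulate_ipcr_reads(insertions, genome, config)
        lookup, rejects = build_lookup(as_pairs(fwd, rev), genome)
        n_truncated = (100 - len(lookup)) * config.ipcr_reads_per_barcode
        assert rejects["barcode_length"] == n_truncated
        assert 0 < len(lookup) < 100


class TestEnrichment:
    def test_half_dose_chromosome(self):
        config = SimConfig(seed=11, n_barcodes=2000)
        genome, annotation = simulate_genome(config)
        insertions = simulate_insertions(genome, annotation, config)
        lookup = insertions.assign(status="unique")
        per_chrom, per_cat = insertion_enrichment(lookup, annotation, config.chrom_sizes)
        ratios = per_chrom.set_index("chrom")["obs_exp"]
        assert abs(ratios["chrX"] - 0.5) < 0.12
        for chrom in ("chr1", "chr2", "chr3"):
            assert abs(ratios[chrom] - 1.0) < 0.25
        # Without weighting, categories match the uniform model too.
        for row in per_cat.itertuples():
            assert abs(row.obs_exp - 1.0) < 0.25

    def test_expressed_gene_weighting_recovered(self):
        config = SimConfig(seed=12, n_barcodes=2000, expressed_weight=1.35)
        genome, annotation = simulate_genome(config)
        insertions = simulate_insertions(genome, annotation, config)
        lookup = insertions.assign(status="unique")
        _, per_cat = insertion_enrichment(lookup, annotation, config.chrom_sizes)
        expressed = per_cat.set_index("category").loc["expressed", "obs_exp"]
        intergenic = per_cat.set_index("category").loc["intergenic", "obs_exp"]
        assert expressed / intergenic == pytest.approx(1.35, abs=0.12)
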