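import numpy as np
import pytest
from Bio.Seq import Seq

from cavekit.errors import DomainError
from cavekit.mutation_analysis import (
    GeneFeature,
    GenomeAnnotation,
    VariantRecord,
    VariantTable,
    all_gene_indices,
    classify_variant,
    compare_series,
    enrichment_trajectory,
    gene_mutation_index,
    homopolymer_shifts,
    normalize_background,
    read_annotation_bed,
    read_annotation_gff3,
    read_variants,
    region_fractions,
    substitution_properties,
    write_annotation_gff3,
    write_variants,
)
from cavekit.synthetic_data import simulate_sequencing


def table_of(freqs_by_pos, sample="s", ref_id="toy"):
    return VariantTable(
        [
            VariantRecord(position=p, ref="G", alt="A", frequency=f, sample=sample)
            for p, f in freqs_by_pos.items()
        ],
        sample=sample,
        reference_id=ref_id,
    )


class TestVariantTypes:
    def test_frequency_bounds(self):
        with pytest.raises(DomainError):
            VariantRecord(position=5, ref="G", alt="A", frequency=1.2)

    def test_ref_must_differ_from_alt(self):
        with pytest.raises(DomainError):
            VariantRecord(position=5, ref="G", alt="G", frequency=0.2)

    def test_duplicate_keys_rejected(self):
        t = VariantTable(sample="s")
        t.add(VariantRecord(5, "G", "A", 0.1))
        with pytest.raises(ValueError):
            t.add(VariantRecord(5, "G", "A", 0.3))


class TestVcfIo:
    def test_single_record(self, tmp_path):
        path = tmp_path / "one.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AF,Number=A,Type=Float,Description="af">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "toy\t7\t.\tG\tA\t.\tPASS\tAF=0.25\n"
        )
        t = read_variants(path, "s1")
        assert len(t) == 1
        rec = next(iter(t))
        assert (rec.position, rec.ref, rec.alt) == (7, "G", "A")
        assert rec.frequency == 0.25

    def test_multiallelic_split(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AF,Number=A,Type=Float,Description="af">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "toy\t7\t.\tG\tA,T\t.\tPASS\tAF=0.1,0.2\n"
        )
        t = read_variants(path)
        assert len(t) == 2
        assert t.frequency((7, "G", "A")) == 0.1
        assert t.frequency((7, "G", "T")) == 0.2

    def test_ad_dp_fallback(self, tmp_path):
        path = tmp_path / "addp.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
            '##INFO=<ID=AD,Number=R,Type=Integer,Description="ad">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "toy\t9\t.\tC\tT\t.\tPASS\tDP=200;AD=150,50\n"
        )
        t = read_variants(path)
        assert t.frequency((9, "C", "T")) == pytest.approx(0.25)

    def test_round_trip_of_simulated_vcf(self, tmp_path):
        rng = np.random.default_rng(5)
        truth = {
            (int(p), "G", "A"): float(f)
            for p, f in zip(
                rng.choice(np.arange(1, 2000), size=50, replace=False),
                rng.uniform(0.005, 0.9, size=50),
            )
        }
        path = tmp_path / "sim.vcf"
        table = simulate_sequencing(
            truth, depth=1000, seed=3, sample="sim", vcf_path=str(path),
            reference_length=2000,
        )
        back = read_variants(path, "sim")
        assert back == table


class TestNormalizeBackground:
    def test_direct_subtraction(self):
        out = normalize_background(table_of({10: 0.30}), table_of({10: 0.05}, "wt"))
        assert out.frequency((10, "G", "A")) == pytest.approx(0.25)

    def test_clamped_records_dropped(self):
        out = normalize_background(table_of({10: 0.02}), table_of({10: 0.04}, "wt"))
        assert len(out) == 0

    def test_absent_wildtype_key_subtracts_zero(self):
        out = normalize_background(table_of({10: 0.30}), table_of({}, "wt"))
        assert out.frequency((10, "G", "A")) == pytest.approx(0.30)

    def test_idempotent_against_empty_wildtype(self):
        sample = table_of({10: 0.3, 20: 0.7})
        once = normalize_background(sample, table_of({}, "wt"))
        twice = normalize_background(once, table_of({}, "wt"))
        assert once == twice

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ValueError):
            normalize_background(
                table_of({10: 0.3}, ref_id="a"), table_of({}, "wt", ref_id="b")
            )

    def test_recovers_truth_from_simulated_background(self):
        # generative oracle: sample = truth + background, wt = background
        rng = np.random.default_rng(21)
        depth = 2000
        truth = {(int(p), "G", "A"): float(f) for p, f in
                 zip(range(10, 310, 3), rng.uniform(0.05, 0.8, size=100))}
        background = {(int(p), "G", "A"): float(f) for p, f in
                      zip(range(10, 310, 6), rng.uniform(0.002, 0.03, size=50))}
        observed = {k: min(1.0, f + background.get(k, 0.0)) for k, f in truth.items()}
        sample = simulate_sequencing(observed, depth, seed=rng, sample="s")
        wt = simulate_sequencing(background, depth, seed=rng, sample="s")
        normed = normalize_background(sample, wt)
        errors = [abs(normed.frequency(k) - f) for k, f in truth.items()]
        assert np.mean(errors) < 2.0 / np.sqrt(depth)


GENES = GenomeAnnotation(
    [
        GeneFeature("g1", 100, 399, "+", "structural"),
        GeneFeature("g2", 500, 799, "+", "regulatory"),
    ],
    reference_id="toy",
    reference_length=1000,
)


class TestGeneMutationIndex:
    def test_threshold_is_strict(self):
        t = table_of({150: 0.009, 160: 0.011, 170: 0.5})
        idx = gene_mutation_index(t, GENES, "g1")
        assert idx.value == pytest.approx(0.511)
        assert idx.n_sites == 2

    def test_exact_threshold_value_excluded(self):
        t = table_of({150: 0.01})
        assert gene_mutation_index(t, GENES, "g1").value == 0.0

    def test_empty_table(self):
        assert gene_mutation_index(VariantTable(), GENES, "g1").value == 0.0

    def test_unknown_gene(self):
        with pytest.raises(KeyError):
            gene_mutation_index(VariantTable(), GENES, "nope")

    def test_zero_threshold_equals_plain_sum(self):
        t = table_of({150: 0.005, 200: 0.4})
        assert gene_mutation_index(t, GENES, "g1", threshold=0.0).value == pytest.approx(
            0.405
        )

    def test_non_increasing_in_threshold(self):
        rng = np.random.default_rng(8)
        t = table_of({int(p): float(f) for p, f in
                      zip(rng.choice(1000, 60, replace=False) + 1, rng.uniform(0, 0.3, 60))})
        vals = [
            gene_mutation_index(t, GENES, "g1", threshold=th).value
            for th in (0.0, 0.01, 0.05, 0.2)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_matches_brute_force_oracle(self):
        # oracle: double loop over records x genes
        rng = np.random.default_rng(17)
        for _ in range(20):
            pos = rng.choice(np.arange(1, 1001), size=40, replace=False)
            fr = rng.uniform(0, 0.5, size=40)
            t = table_of({int(p): float(f) for p, f in zip(pos, fr)})
            for gene in GENES.features:
                expected = 0.0
                for rec in t:
                    if rec.frequency > 0.01 and gene.start <= rec.position <= gene.end:
                        expected += rec.frequency
                got = gene_mutation_index(t, GENES, gene.gene_id).value
                assert got == pytest.approx(expected, abs=1e-15)


class TestRegionFractions:
    def test_all_structural(self):
        fr = region_fractions(table_of({150: 0.5, 200: 0.3}), GENES)
        assert fr == pytest.approx({"structural": 1.0, "regulatory": 0.0, "non_coding": 0.0})

    def test_split_between_categories(self):
        fr = region_fractions(table_of({150: 0.4, 900: 0.4}), GENES)
        assert fr["structural"] == pytest.approx(0.5)
        assert fr["non_coding"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        t = table_of({int(p): float(f) for p, f in
                      zip(rng.choice(1000, 80, replace=False) + 1, rng.uniform(0.02, 0.6, 80))})
        fr = region_fractions(t, GENES)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_is_all_zero(self):
        fr = region_fractions(VariantTable(), GENES)
        assert all(v == 0.0 for v in fr.values())

    def test_count_weighted_option(self):
        t = table_of({150: 0.9, 900: 0.1})
        fr = region_fractions(t, GENES, weight_by="count")
        assert fr["structural"] == pytest.approx(0.5)


class TestEnrichmentTrajectory:
    def test_variant_only_in_final_round(self):
        tables = [table_of({}, "r1"), table_of({}, "r2"), table_of({50: 0.4}, "r3")]
        traj = enrichment_trajectory(tables)
        np.testing.assert_allclose(traj.frequencies[(50, "G", "A")], [0, 0, 0.4])

    def test_saturating_flag(self):
        tables = [table_of({50: 0.1}, "r1"), table_of({50: 0.97}, "r2")]
        traj = enrichment_trajectory(tables)
        assert (50, "G", "A") in traj.saturating

    def test_needs_two_rounds(self):
        with pytest.raises(DomainError):
            enrichment_trajectory([table_of({})])

    def test_beneficial_allele_saturates_in_simulation(self, evolution_arms):
        # simulation oracle: designated stabilizing alleles under the full
        # protocol collectively approach saturation
        n_saturated = 0
        for traj in evolution_arms["full"]:
            total = sum(
                traj.final_frequencies().get(k, 0.0) for k in traj.stabilizing_keys
            )
            if total >= 0.95:
                n_saturated += 1
        assert n_saturated >= 18

    def test_neutral_alleles_stay_rare(self, evolution_arms):
        n_low = 0
        n_total = 0
        for traj in evolution_arms["full"]:
            for k in traj.neutral_keys:
                n_total += 1
                if traj.final_frequencies().get(k, 0.0) < 0.2:
                    n_low += 1
        assert n_low / n_total >= 0.95


class TestCompareSeries:
    def test_identical_inputs(self):
        idx = {"g1": 0.5, "g2": 0.2, "g3": 0.9}
        cmp = compare_series(idx, dict(idx))
        assert (cmp.table["index_a"] == cmp.table["index_b"]).all()
        assert cmp.spearman_rho == pytest.approx(1.0)

    def test_homolog_map_pairing(self):
        a = {"T3p37": 1.2, "T3p42": 0.7, "T3p43": 0.3}
        b = {"T7p42": 1.1, "T7p46": 0.6, "T7p47": 0.2}
        hmap = {"T3p37": "T7p42", "T3p42": "T7p46", "T3p43": "T7p47"}
        cmp = compare_series(a, b, hmap)
        assert len(cmp.table) == 3
        row = cmp.table[cmp.table.gene_a == "T3p37"].iloc[0]
        assert row.gene_b == "T7p42"
        assert row.index_b == pytest.approx(1.1)

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError, match="unmatched"):
            compare_series({"x": 1.0}, {"y": 2.0})

    def test_matches_brute_force_pairing_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            a = {f"a{i}": float(rng.uniform(0, 2)) for i in range(8)}
            b = {f"b{i}": float(rng.uniform(0, 2)) for i in range(8)}
            keys = rng.permutation(8)
            hmap = {f"a{i}": f"b{keys[i]}" for i in range(8)}
            cmp = compare_series(a, b, hmap)
            expected = {(ga, gb): (a[ga], b[gb]) for ga, gb in hmap.items()}
            for _, row in cmp.table.iterrows():
                ea, eb = expected[(row.gene_a, row.gene_b)]
                assert row.index_a == ea and row.index_b == eb


class TestAnnotationIo:
    def test_gff3_round_trip(self, tmp_path, toy_annotation):
        path = tmp_path / "genes.gff3"
        write_annotation_gff3(toy_annotation, path)
        back = read_annotation_gff3(path)
        assert back.gene_ids() == toy_annotation.gene_ids()
        for gid in back.gene_ids():
            f1, f2 = back.gene(gid), toy_annotation.gene(gid)
            assert (f1.start, f1.end, f1.strand, f1.category) == (
                f2.start, f2.end, f2.strand, f2.category
            )

    def test_bed_is_converted_to_one_based(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("toy\t10\t40\tgeneA\tstructural\t+\n")
        ann = read_annotation_bed(path)
        gene = ann.gene("geneA")
        assert (gene.start, gene.end) == (11, 40)


class TestClassifyVariant:
    def rec(self, pos, ref, alt):
        return VariantRecord(position=pos, ref=ref, alt=alt, frequency=0.5)

    def test_intergenic(self, toy_annotation, toy_reference):
        c = classify_variant(
            self.rec(5, toy_reference[4], "A" if toy_reference[4] != "A" else "C"),
            toy_annotation,
            toy_reference,
        )
        assert c.kind == "intergenic"

    def test_start_codon_missense(self, toy_annotation, toy_reference):
        # geneA starts ATG at 11; ATG->ATA is M1I
        assert toy_reference[10:13] == "ATG"
        c = classify_variant(self.rec(13, "G", "A"), toy_annotation, toy_reference)
        assert c.kind == "missense"
        assert c.aa_change == "M1I"

    def test_synonymous_third_position(self, toy_annotation, toy_reference):
        # codon 2 of geneA is AAA (K); AAA->AAG stays K
        assert toy_reference[13:16] == "AAA"
        c = classify_variant(self.rec(16, "A", "G"), toy_annotation, toy_reference)
        assert c.kind == "synonymous"
        assert c.aa_from == "K"

    def test_frameshift_and_inframe_indel(self, toy_annotation, toy_reference):
        fs = classify_variant(
            self.rec(20, toy_reference[19], toy_reference[19] + "AT"),
            toy_annotation,
            toy_reference,
        )
        assert fs.kind == "frameshift"
        inframe = classify_variant(
            self.rec(20, toy_reference[19], toy_reference[19] + "ATT"),
            toy_annotation,
            toy_reference,
        )
        assert inframe.kind == "inframe_indel"

    def test_boundary_flag(self, toy_annotation, toy_reference):
        # deletion anchored inside geneA extending past its end (gene ends at 40)
        ref_span = toy_reference[38:43]
        c = classify_variant(
            self.rec(39, ref_span, ref_span[0]), toy_annotation, toy_reference
        )
        assert c.kind == "boundary"

    def test_ref_mismatch_rejected(self, toy_annotation, toy_reference):
        wrong = "A" if toy_reference[14] != "A" else "C"
        with pytest.raises(DomainError):
            classify_variant(self.rec(15, wrong, "G"), toy_annotation, toy_reference)

    @pytest.mark.parametrize("strand_gene", ["geneA", "geneB"])
    def test_matches_full_retranslation_oracle(
        self, strand_gene, toy_annotation, toy_reference
    ):
        # oracle: re-translate the whole mutated gene and diff the proteins
        gene = toy_annotation.gene(strand_gene)
        rng = np.random.default_rng(hash(strand_gene) % 2**32)
        for _ in range(1000):
            pos = int(rng.integers(gene.start, gene.end + 1))
            ref_base = toy_reference[pos - 1]
            alt_base = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            c = classify_variant(
                self.rec(pos, ref_base, alt_base), toy_annotation, toy_reference
            )
            mutated = (
                toy_reference[: pos - 1] + alt_base + toy_reference[pos:]
            )

            def protein(seq):
                sub = seq[gene.start - 1 : gene.end]
                if gene.strand == "-":
                    sub = str(Seq(sub).reverse_complement())
                return str(Seq(sub).translate())

            p_ref, p_alt = protein(toy_reference), protein(mutated)
            if p_ref == p_alt:
                expected = "synonymous"
            else:
                i = next(j for j in range(len(p_ref)) if p_ref[j] != p_alt[j])
                expected = "nonsense" if p_alt[i] == "*" else "missense"
            assert c.kind == expected, (pos, ref_base, alt_base)
            if expected != "synonymous":
                assert c.aa_from == p_ref[i] and c.aa_to == p_alt[i]


class TestSubstitutionProperties:
    def test_identity_is_zero(self):
        p = substitution_properties("L", "L")
        assert p.delta_hydrophobicity == 0.0 and p.delta_volume == 0.0

    def test_glycine_to_tryptophan_is_larger(self):
        assert substitution_properties("G", "W").delta_volume > 0

    def test_unknown_residue(self):
        with pytest.raises(DomainError):
            substitution_properties("G", "Z")

    def test_hydrophobic_biased_substitutions_have_positive_mean(self):
        # generative oracle: substitutions engineered toward hydrophobic,
        # bulky residues must show positive mean deltas
        rng = np.random.default_rng(9)
        residues = list("ARNDCQEGHILKMFPSTWYV")
        hydrophobic = list("ILVFMW")
        dh, dv = [], []
        for _ in range(500):
            src = str(rng.choice(residues))
            dst = str(rng.choice(hydrophobic))
            if src == dst:
                continue
            p = substitution_properties(src, dst)
            dh.append(p.delta_hydrophobicity)
            dv.append(p.delta_volume)
        assert np.mean(dh) > 0
        assert np.mean(dv) > 0


class TestHomopolymerShifts:
    def test_insertion_inside_run(self):
        ref = "ATAGGGGGGATCT"  # G x 6 at positions 4-9
        t = VariantTable(
            [VariantRecord(position=5, ref="G", alt="GG", frequency=0.3)], sample="s"
        )
        shifts = homopolymer_shifts(t, ref)
        assert len(shifts) == 1
        s = shifts[0]
        assert (s.run_start, s.run_length, s.length_change) == (4, 6, 1)

    def test_snv_inside_run_excluded(self):
        ref = "ATAGGGGGGATCT"
        t = VariantTable([VariantRecord(5, "G", "A", 0.3)], sample="s")
        assert homopolymer_shifts(t, ref) == []

    def test_short_runs_ignored(self):
        ref = "ATAGGGATCT"  # G x 3 < min_run
        t = VariantTable([VariantRecord(4, "G", "GG", 0.3)], sample="s")
        assert homopolymer_shifts(t, ref) == []

    def test_matches_brute_force_scanner(self):
        # oracle: independent linear scan for runs
        rng = np.random.default_rng(14)
        for _ in range(20):
            ref = "".join(rng.choice(list("ACGT"), size=300, p=[0.2, 0.2, 0.4, 0.2]))
            runs = []
            i = 0
            while i < len(ref):
                if ref[i] == "G":
                    j = i
                    while j < len(ref) and ref[j] == "G":
                        j += 1
                    if j - i >= 4:
                        runs.append((i + 1, j - i))
                    i = j
                else:
                    i += 1
            records = []
            for pos in rng.choice(np.arange(1, 300), size=15, replace=False):
                pos = int(pos)
                records.append(
                    VariantRecord(pos, ref[pos - 1], ref[pos - 1] + "G", 0.2)
                )
            t = VariantTable(records, sample="s")
            expected = sorted(
                (start, length)
                for rec in records
                for (start, length) in runs
                if start <= rec.position <= start + length - 1
            )
            got = sorted((s.run_start, s.run_length) for s in homopolymer_shifts(t, ref))
            assert got == expected
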