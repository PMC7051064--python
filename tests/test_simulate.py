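import math

import numpy as np
import pytest

from circmt import (generate_background, generate_reference, plant_variants,
                    simulate_qpcr, simulate_reads)
from circmt.simulate import QpcrTruth, simulate_sample_cq


class TestGenerateReference:
    def test_length_and_gc(self):
        g = generate_reference(16299, 0.38, seed=7)
        assert g.length == 16299
        gc = sum(1 for b in g.sequence if b in "GC") / g.length  # independent tally
        assert 0.35 <= gc <= 0.41

    def test_seed_determinism(self):
        assert generate_reference(200, 0.5, 1).sequence == generate_reference(200, 0.5, 1).sequence
        assert generate_reference(200, 0.5, 1).sequence != generate_reference(200, 0.5, 2).sequence

    @pytest.mark.parametrize("length,gc", [(100, 0.4), (16299, 0.0), (16299, 1.0)])
    def test_invalid_parameters(self, length, gc):
        with pytest.raises(ValueError):
            generate_reference(length, gc, seed=0)


class TestGenerateBackground:
    def test_numt_realized_divergence(self, toy_genome):
        bg = generate_background(toy_genome, 20000, 3, 500, 0.08, seed=5)
        doubled = toy_genome.sequence * 2
        for numt in bg.numts:
            src = doubled[numt.mt_source_start:numt.mt_source_start + numt.source_length]
            ins = bg.sequence[numt.nuclear_start:numt.nuclear_start + numt.source_length]
            realized = sum(a != b for a, b in zip(src, ins)) / numt.source_length
            assert 0.5 * numt.divergence <= realized <= 1.5 * numt.divergence

    def test_intervals_inside_background(self, toy_genome):
        bg = generate_background(toy_genome, 10000, 4, 300, 0.05, seed=1)
        for numt in bg.numts:
            assert 0 <= numt.nuclear_start
            assert numt.nuclear_start + numt.source_length <= bg.length


class TestPlantVariants:
    def test_structure_and_distinctness(self, mt_genome):
        truth = plant_variants(mt_genome, 50, 100, 0.5, 0.05,
                               tissues=("brain", "liver"), seed=3)
        assert len(truth.germline_variants) == 50
        assert all(len(v) == 100 for v in truth.somatic_variants.values())
        positions = [v.position for v in truth.germline_variants]
        for tissue_vars in truth.somatic_variants.values():
            positions += [v.position for v in tissue_vars]
        assert len(positions) == len(set(positions)) == 250
        for vs in ([truth.germline_variants] + list(truth.somatic_variants.values())):
            for v in vs:
                assert v.ref == mt_genome.base(v.position)
                assert v.alt != v.ref

    def test_no_germline(self, mt_genome):
        truth = plant_variants(mt_genome, 0, 10, 0.5, 0.05, seed=3)
        assert truth.germline_variants == []

    def test_determinism_byte_identical(self, mt_genome):
        a = plant_variants(mt_genome, 5, 5, 0.5, 0.05, seed=9).to_frame().to_csv()
        b = plant_variants(mt_genome, 5, 5, 0.5, 0.05, seed=9).to_frame().to_csv()
        assert a == b

    def test_too_many_variants(self, toy_genome):
        with pytest.raises(ValueError):
            plant_variants(toy_genome, 1500, 500, 0.5, 0.05, seed=0)


class TestSimulateReads:
    def test_total_mt_bases_near_target(self, mt_genome):
        truth = plant_variants(mt_genome, 0, 0, 0.5, 0.05, seed=1)
        reads = simulate_reads(mt_genome, None, truth, "brain", depth_mt=200.0,
                               purified=True, seed=4)
        # independent tally: sum of sequence lengths over all mates
        total = sum(len(p.seq1) + len(p.seq2) for p in reads.pairs)
        assert abs(total - 200 * 16299) / (200 * 16299) < 0.05

    def test_purified_has_no_nuclear_reads(self, toy_genome):
        bg = generate_background(toy_genome, 10000, 2, 300, 0.05, seed=2)
        truth = plant_variants(toy_genome, 0, 0, 0.5, 0.05, seed=1)
        pure = simulate_reads(toy_genome, bg, truth, "brain", depth_mt=20.0,
                              depth_nuc=20.0, read_len=100, purified=True, seed=6)
        assert all(p.name.startswith("mt|") for p in pure.pairs)

    def test_purified_unpurified_share_mt_stream(self, toy_genome):
        bg = generate_background(toy_genome, 10000, 2, 300, 0.05, seed=2)
        truth = plant_variants(toy_genome, 2, 2, 0.5, 0.1, seed=1)
        pure = simulate_reads(toy_genome, bg, truth, "brain", depth_mt=20.0,
                              read_len=100, purified=True, seed=6)
        unpure = simulate_reads(toy_genome, bg, truth, "brain", depth_mt=20.0,
                                depth_nuc=10.0, read_len=100, purified=False, seed=6)
        mt_unpure = [p for p in unpure.pairs if p.name.startswith("mt|")]
        assert [(p.name, p.seq1, p.seq2) for p in pure.pairs] == \
               [(p.name, p.seq1, p.seq2) for p in mt_unpure]
        assert len(unpure.pairs) > len(pure.pairs)

    def test_origin_wrap_fraction(self, toy_genome):
        """Fragments start uniformly on the circle, so the fraction of mates
        spanning the origin matches the wrap probability (read_len-1)/L."""
        truth = plant_variants(toy_genome, 0, 0, 0.5, 0.05, seed=1)
        read_len, L = 100, toy_genome.length
        reads = simulate_reads(toy_genome, None, truth, "brain", depth_mt=100.0,
                               read_len=read_len, error_rate=0.0, purified=True, seed=8)
        linear = toy_genome.sequence
        doubled = linear * 2
        rc = str.maketrans("ACGT", "TGCA")
        n_wrap = n_mates = 0
        for p in reads.pairs:
            for seq in (p.seq1, p.seq2[::-1].translate(rc)):
                assert seq in doubled  # error-free mate must occur on the circle
                n_mates += 1
                n_wrap += seq not in linear
        p_wrap = (read_len - 1) / L
        sigma = math.sqrt(p_wrap * (1 - p_wrap) / n_mates)
        assert abs(n_wrap / n_mates - p_wrap) < 3 * sigma

    def test_empirical_error_rate(self, toy_genome):
        """Diffing an error-injected run against a zero-error run with the
        same seed isolates exactly the injected substitutions."""
        truth = plant_variants(toy_genome, 0, 0, 0.5, 0.05, seed=1)
        err = 0.005
        clean = simulate_reads(toy_genome, None, truth, "brain", depth_mt=50.0,
                               read_len=100, error_rate=0.0, purified=True, seed=3)
        noisy = simulate_reads(toy_genome, None, truth, "brain", depth_mt=50.0,
                               read_len=100, error_rate=err, purified=True, seed=3)
        n_diff = n_tot = 0
        for cp, ep in zip(clean.pairs, noisy.pairs):
            for a, b in ((cp.seq1, ep.seq1), (cp.seq2, ep.seq2)):
                n_diff += sum(x != y for x, y in zip(a, b))
                n_tot += len(a)
        sigma = math.sqrt(err * (1 - err) / n_tot)
        assert abs(n_diff / n_tot - err) < 3 * sigma

    def test_allele_fraction_conservation(self, toy_genome):
        """Realized alt fraction at a planted site stays within 3 binomial
        sigma of its truth fraction (counted by raw substring inspection)."""
        from tests.conftest import make_truth, variant_at
        v = variant_at(toy_genome, 1000, 0.3)
        truth = make_truth(toy_genome, {"brain": [v]}, error_rate=0.0)
        reads = simulate_reads(toy_genome, None, truth, "brain", depth_mt=200.0,
                               read_len=100, purified=True, seed=5)
        # every error-free mate is an exact substring of either the reference
        # circle or the alt-substituted circle; locate it and read off the allele
        L = toy_genome.length
        i = v.position - 1
        ref_doubled = toy_genome.sequence * 2
        alt_circle = toy_genome.sequence[:i] + v.alt + toy_genome.sequence[i + 1:]
        alt_doubled = alt_circle * 2
        rc = str.maketrans("ACGT", "TGCA")
        ref_n = alt_n = 0
        for p in reads.pairs:
            for seq in (p.seq1, p.seq2[::-1].translate(rc)):
                pos = ref_doubled.find(seq)
                if pos >= 0:
                    if (i - pos) % L < len(seq):
                        ref_n += 1
                else:
                    pos = alt_doubled.find(seq)
                    assert pos >= 0, "mate traces to neither allele"
                    off = (i - pos) % L
                    assert off < len(seq) and seq[off] == v.alt
                    alt_n += 1
        depth = ref_n + alt_n
        assert depth > 50
        sigma = math.sqrt(v.allele_fraction * (1 - v.allele_fraction) / depth)
        assert abs(alt_n / depth - v.allele_fraction) < 3 * sigma

    def test_read_len_validation(self, toy_genome):
        truth = plant_variants(toy_genome, 0, 0, 0.5, 0.05, seed=1)
        with pytest.raises(ValueError):
            simulate_reads(toy_genome, None, truth, "brain", read_len=2000, seed=0)

    def test_fastq_syntax(self, toy_genome, tmp_path):
        truth = plant_variants(toy_genome, 0, 0, 0.5, 0.05, seed=1)
        reads = simulate_reads(toy_genome, None, truth, "brain", depth_mt=5.0,
                               read_len=100, purified=True, seed=2)
        p1, p2 = reads.write_fastq(tmp_path / "s")
        from Bio import SeqIO
        recs = list(SeqIO.parse(str(p1), "fastq"))
        assert len(recs) == len(reads.pairs)
        assert all(len(r.seq) == 100 for r in recs)


class TestSimulateQpcr:
    def test_tenfold_step_closed_form(self):
        cq = simulate_qpcr(QpcrTruth(2.0, 2.0, 0.0, 1000.0), 4, 5, seed=0)
        sub = cq[cq.assay == "mB2M"].groupby("dilution")["Cq"].mean()
        steps = np.diff(sub.to_numpy())
        assert np.allclose(steps, math.log2(10))

    def test_assay_separation_closed_form(self):
        cq = simulate_qpcr(QpcrTruth(2.0, 2.0, 0.0, 1000.0), 4, 5, seed=0)
        d0 = cq[cq.dilution == 0].groupby("assay")["Cq"].mean()
        assert d0["mB2M"] - d0["mMito"] == pytest.approx(math.log2(1000), abs=1e-9)

    def test_default_design_shape(self):
        cq = simulate_qpcr(QpcrTruth(), seed=0)
        counts = cq.groupby("assay").size()
        assert (counts == 4 * 5).all()

    def test_amp_factor_validation(self):
        with pytest.raises(ValueError):
            QpcrTruth(amp_factor_nuclear=1.0)
        with pytest.raises(ValueError):
            QpcrTruth(amp_factor_mito=2.5)

    def test_determinism(self):
        t = QpcrTruth(2.0, 1.9, 0.2, 500.0)
        a = simulate_qpcr(t, seed=4).to_csv()
        assert a == simulate_qpcr(t, seed=4).to_csv()
        assert a != simulate_qpcr(t, seed=5).to_csv()

    def test_sample_cq_layout(self):
        cq = simulate_sample_cq(QpcrTruth(2.0, 2.0, 0.0, 100.0), replicates=3, seed=0)
        assert len(cq) == 6 and set(cq.dilution) == {0}
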