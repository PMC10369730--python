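import warnings

import numpy as np
import pytest

from rsnpscan.diffbind import (MotifNullModel, UncalibratedMotifError,
                               batch_diff_scores, binding_pvalue,
                               diff_binding_pvalue, diff_binding_score,
                               estimate_scale, max_binding_score, scan_snps,
                               score_distribution)
from rsnpscan.genome import Genome, revcomp
from rsnpscan.gwas import SnpRecord
from rsnpscan.motifs import MotifCounts, counts_to_pwm

BASES = "ACGT"
IDX = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# independent oracles

def brute_max_score(seq, pos0, allele, pwm):
    """Exhaustive enumeration over every offset and strand."""
    s = seq[:pos0] + allele + seq[pos0 + 1:]
    m = len(pwm)
    best = (-np.inf, -1, "+")
    for off in range(0, len(s) - m + 1):
        if not (off <= pos0 < off + m):
            continue
        window = s[off:off + m]
        for strand in "+-":
            w = revcomp(window) if strand == "-" else window
            score = sum(pwm.logodds[i, IDX[w[i]]] for i in range(m))
            if score > best[0]:
                best = (score, off, strand)
    return best


def brute_distribution(pwm, bg):
    """Exact window-score distribution by enumerating all 4^m sequences."""
    m = len(pwm)
    scores, probs = [], []
    for code in range(4 ** m):
        p = 1.0
        score = 0.0
        c = code
        for i in range(m):
            b = c % 4
            c //= 4
            p *= bg[b]
            score += pwm.logodds[i, b]
        scores.append(score)
        probs.append(p)
    return np.array(scores), np.array(probs)


def random_pwm(rng, m):
    counts = rng.integers(1, 50, size=(m, 4)).astype(float)
    return counts_to_pwm(MotifCounts(id="r", name="r", counts=counts))


def snp(rsid, pos, ref, alt, chrom="c"):
    return SnpRecord(rsid=rsid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                     role="panel")


# ---------------------------------------------------------------------------

class TestMaxBindingScore:
    def test_uniform_pwm_scores_zero(self, rng):
        pwm = counts_to_pwm(MotifCounts(id="u", name="u",
                                        counts=np.full((4, 4), 5.0)))
        g = Genome({"c": "ACGTACGTACGT"})
        score, _, _ = max_binding_score(g, "c", 6, "A", pwm)
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_single_position_motif_both_strands(self):
        # strong A-motif: allele A scores on '+', allele T on '-' (reads A)
        counts = np.array([[97, 1, 1, 1.0]])
        pwm = counts_to_pwm(MotifCounts(id="a", name="a", counts=counts),
                            pseudocount=0.0)
        g = Genome({"c": "GGGGG"})
        expected = np.log2(0.97 / 0.25)
        sa, _, stra = max_binding_score(g, "c", 3, "A", pwm)
        st_, _, strt = max_binding_score(g, "c", 3, "T", pwm)
        assert sa == pytest.approx(expected, abs=1e-9)
        assert st_ == pytest.approx(expected, abs=1e-9)
        assert (stra, strt) == ("+", "-")
        assert expected == pytest.approx(1.9560, abs=1e-3)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(300):
            m = int(rng.integers(1, 7))
            n = int(rng.integers(m, 51))
            seq = "".join(rng.choice(list(BASES), size=n))
            pwm = random_pwm(rng, m)
            pos0 = int(rng.integers(0, n))
            allele = BASES[rng.integers(0, 4)]
            g = Genome({"c": seq})
            got = max_binding_score(g, "c", pos0 + 1, allele, pwm)
            exp = brute_max_score(seq, pos0, allele, pwm)
            if not np.isfinite(exp[0]):
                assert not np.isfinite(got[0])
                continue
            assert got[0] == pytest.approx(exp[0], abs=1e-9)
            # the reported window must itself achieve the maximum (ties
            # between numerically equal windows may resolve either way)
            s2 = seq[:pos0] + allele + seq[pos0 + 1:]
            window = s2[got[1]:got[1] + m]
            w = revcomp(window) if got[2] == "-" else window
            rescored = sum(pwm.logodds[i, IDX[w[i]]] for i in range(m))
            assert rescored == pytest.approx(exp[0], abs=1e-9)

    def test_no_window_fits_near_contig_end(self):
        pwm = random_pwm(np.random.default_rng(0), 5)
        g = Genome({"c": "ACG"})
        score, _, _ = max_binding_score(g, "c", 2, "C", pwm)
        assert not np.isfinite(score)


class TestScoreDistribution:
    def test_uniform_pwm_point_mass(self):
        pwm = counts_to_pwm(MotifCounts(id="u", name="u",
                                        counts=np.full((3, 4), 5.0)))
        dist = score_distribution(pwm)
        assert len(dist.support) == 1
        assert binding_pvalue(0.0, dist) == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            m = int(rng.integers(1, 7))
            pwm = random_pwm(rng, m)
            dist = score_distribution(pwm)
            scores, probs = brute_distribution(pwm, pwm.background)
            for q in rng.uniform(scores.min(), scores.max(), size=5):
                exact = probs[scores >= q - 1e-9].sum()
                # binning can shift mass by one lattice step per position
                lo = probs[scores >= q + 0.011 * m].sum()
                hi = probs[scores >= q - 0.011 * m].sum()
                assert lo - 1e-12 <= dist.sf(q) <= hi + 1e-12
                assert dist.sf(q) == pytest.approx(exact, abs=hi - lo + 1e-9)

    def test_distribution_bounds(self, rng):
        pwm = random_pwm(rng, 4)
        dist = score_distribution(pwm)
        assert dist.sf(dist.min_score) == pytest.approx(1.0, abs=1e-9)
        assert dist.sf(dist.max_score + 1.0) == 0.0

    def test_two_position_toy_tail_by_hand(self):
        counts = np.array([[10, 10, 0, 0], [0, 0, 10, 10.0]])
        pwm = counts_to_pwm(MotifCounts(id="t", name="t", counts=counts),
                            pseudocount=0.0)
        dist = score_distribution(pwm)
        # 16 sequences: 4 score 2 bits ({A,C}x{G,T}), the rest -inf-ish
        assert dist.sf(2.0) == pytest.approx(0.25, abs=1e-9)
        assert dist.sf(dist.min_score) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_bin(self, rng):
        with pytest.raises(ValueError):
            score_distribution(random_pwm(rng, 2), bin=0)


class TestDiffBinding:
    def setup_case(self, rng, m=5, n=60):
        seq = "".join(rng.choice(list(BASES), size=n))
        pwm = random_pwm(rng, m)
        return Genome({"c": seq}), seq, pwm

    def test_degenerate_identical_alleles(self, rng):
        g, seq, pwm = self.setup_case(rng)
        s = snp("rs1", 30, seq[29], seq[29])
        res = diff_binding_score(g, s, pwm)
        assert res.D == 0.0

    def test_allele_swap_antisymmetry(self, rng):
        g, seq, pwm = self.setup_case(rng)
        dist = score_distribution(pwm)
        ref = seq[29]
        alt = next(b for b in BASES if b != ref)
        fwd = diff_binding_score(g, snp("rs1", 30, ref, alt), pwm, dist=dist)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rev = diff_binding_score(g, snp("rs1", 30, alt, ref), pwm,
                                     dist=dist, check_ref=False)
        assert rev.D == pytest.approx(-fwd.D, abs=1e-12)
        assert rev.p_bind_ref == fwd.p_bind_alt
        assert rev.p_bind_alt == fwd.p_bind_ref
        model = MotifNullModel("r", scale=1.3, n_null=100, score_dist=dist)
        assert diff_binding_pvalue(fwd.D, model) == \
            pytest.approx(diff_binding_pvalue(rev.D, model))

    def test_ref_mismatch_skipped_with_warning(self, rng):
        g, seq, pwm = self.setup_case(rng)
        bad_ref = next(b for b in BASES if b != seq[29])
        with pytest.warns(UserWarning, match="does not match"):
            res = diff_binding_score(g, snp("rs1", 30, bad_ref, "A"), pwm)
        assert res is None

    def test_indel_skipped_with_warning(self, rng):
        g, seq, pwm = self.setup_case(rng)
        with pytest.warns(UserWarning, match="not a biallelic SNV"):
            res = diff_binding_score(g, snp("rs1", 30, seq[29], "AT"), pwm)
        assert res is None

    def test_batch_equals_scalar(self, rng):
        g, seq, pwm = self.setup_case(rng, m=6, n=200)
        dist = score_distribution(pwm)
        pos, refs, alts, scalar = [], [], [], []
        for p0 in range(10, 150, 7):
            ref = seq[p0]
            alt = BASES[(IDX[ref] + 1) % 4]
            res = diff_binding_score(g, snp(f"r{p0}", p0 + 1, ref, alt),
                                     pwm, dist=dist)
            pos.append(p0)
            refs.append(IDX[ref])
            alts.append(IDX[alt])
            scalar.append(res.D)
        batch = batch_diff_scores(g, "c", np.array(pos), np.array(refs),
                                  np.array(alts), pwm)
        np.testing.assert_allclose(batch, scalar, atol=1e-9)


class TestNullModel:
    def test_laplace_tail_closed_form(self):
        dist = score_distribution(random_pwm(np.random.default_rng(1), 3))
        model = MotifNullModel("m", scale=0.8, n_null=500, score_dist=dist)
        assert diff_binding_pvalue(0.0, model) == 1.0
        assert diff_binding_pvalue(0.8 * np.log(2), model) == \
            pytest.approx(0.5, abs=1e-12)
        assert diff_binding_pvalue(-0.8 * np.log(2), model) == \
            pytest.approx(0.5, abs=1e-12)

    def test_pvalue_monotone_in_abs_d(self):
        dist = score_distribution(random_pwm(np.random.default_rng(1), 3))
        model = MotifNullModel("m", scale=1.1, n_null=500, score_dist=dist)
        ds = np.linspace(0, 10, 40)
        ps = [diff_binding_pvalue(d, model) for d in ds]
        assert (np.diff(ps) < 0).all()

    def test_scale_is_mean_absolute_d(self, rng):
        seq = "".join(rng.choice(list(BASES), size=500))
        g = Genome({"c": seq})
        pwm = random_pwm(rng, 5)
        panel = []
        for p0 in range(5, 400, 4):
            ref = seq[p0]
            panel.append(snp(f"r{p0}", p0 + 1, ref,
                             BASES[(IDX[ref] + 2) % 4]))
        model = estimate_scale(pwm, g, panel, min_scoreable=10)
        dist = score_distribution(pwm)
        oracle = []
        for s in panel:
            res = diff_binding_score(g, s, pwm, dist=dist)
            oracle.append(abs(res.D))
        assert model.calibrated
        assert model.scale == pytest.approx(np.mean(oracle), abs=1e-9)
        assert model.n_null == len(oracle)

    def test_scale_stable_across_null_panels(self, rng):
        """The fitted Laplace scale varies by < 10% between independent
        2,000-SNP null panels on the same genome."""
        seq = "".join(rng.choice(list(BASES), size=50_000))
        g = Genome({"c": seq})
        counts = rng.integers(1, 200, size=(10, 4)).astype(float)
        pwm = counts_to_pwm(MotifCounts(id="s", name="s", counts=counts))
        scales = []
        for rep in range(3):
            rep_rng = np.random.default_rng(1000 + rep)
            panel = []
            for _ in range(2000):
                p0 = int(rep_rng.integers(0, len(seq)))
                ref = seq[p0]
                alt = BASES[(IDX[ref] + int(rep_rng.integers(1, 4))) % 4]
                panel.append(snp(f"r{len(panel)}", p0 + 1, ref, alt))
            scales.append(estimate_scale(pwm, g, panel).scale)
        spread = (max(scales) - min(scales)) / np.mean(scales)
        assert spread <= 0.10

    def test_uniform_pwm_flagged_uncalibrated(self, rng):
        pwm = counts_to_pwm(MotifCounts(id="u", name="u",
                                        counts=np.full((4, 4), 5.0)))
        seq = "".join(rng.choice(list(BASES), size=300))
        g = Genome({"c": seq})
        panel = [snp(f"r{i}", i + 1, seq[i], BASES[(IDX[seq[i]] + 1) % 4])
                 for i in range(10, 250)]
        with pytest.warns(UserWarning, match="uncalibrated"):
            model = estimate_scale(pwm, g, panel, min_scoreable=10)
        assert not model.calibrated

    def test_too_few_null_snps_flagged(self, rng):
        seq = "".join(rng.choice(list(BASES), size=100))
        g = Genome({"c": seq})
        pwm = random_pwm(rng, 5)
        panel = [snp("r1", 50, seq[49], BASES[(IDX[seq[49]] + 1) % 4])]
        with pytest.warns(UserWarning, match="uncalibrated"):
            model = estimate_scale(pwm, g, panel, min_scoreable=100)
        assert not model.calibrated


class TestScan:
    def make_models(self, pwms, scale=1.0):
        return {p.id: MotifNullModel(p.id, scale=scale, n_null=1000,
                                     score_dist=score_distribution(p))
                for p in pwms}

    def test_filters_off_emits_every_scoreable_pair(self, rng):
        seq = "".join(rng.choice(list(BASES), size=80))
        g = Genome({"c": seq})
        pwms = [random_pwm(rng, 4), random_pwm(rng, 5)]
        pwms[0].id, pwms[1].id = "m1", "m2"
        snps = [snp(f"r{i}", i + 1, seq[i], BASES[(IDX[seq[i]] + 1) % 4])
                for i in range(10, 40, 3)]
        out = scan_snps(snps, pwms, g, self.make_models(pwms),
                        p_bind_max=1.0, p_diff_max=1.0)
        assert len(out) == len(snps) * len(pwms)
        keys = [(r.snp_id, r.p_diff) for r in out]
        assert keys == sorted(keys)

    def test_uncalibrated_motif_is_hard_error(self, rng):
        seq = "".join(rng.choice(list(BASES), size=80))
        g = Genome({"c": seq})
        pwm = random_pwm(rng, 4)
        model = MotifNullModel(pwm.id, scale=0.0, n_null=0,
                               score_dist=score_distribution(pwm),
                               calibrated=False)
        with pytest.raises(UncalibratedMotifError):
            scan_snps([snp("r1", 20, seq[19], "A")], [pwm], g,
                      {pwm.id: model})
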