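import numpy as np
import pandas as pd
import pytest

from haplopaint.data_model import (
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    SampleMetadata,
    ValidationError,
)
from haplopaint.painting import (
    CopyingModel,
    cleaner_painting,
    consensus,
    detect_deviant_regions,
    fit_em,
    forward_backward,
    paint_panel,
    sample_paintings,
    summarize_ancestry,
    watterson_miscopy,
)
from haplopaint.painting.summary import PaintingConsensus
from haplopaint.synthetic_data import simulate_mosaic_recipients

import oracles
from conftest import make_metadata


def tiny_panel(seed=0, n_donors=4, n_snps=3, pops=(1, 1, 2, 2), rho=0.13, theta=0.05):
    rng = np.random.default_rng(seed)
    ids = [f"d{i}" for i in range(n_donors)]
    donors = GenotypeMatrix(
        ids,
        [f"s{j}" for j in range(n_snps)],
        rng.integers(0, 2, (n_donors, n_snps)).astype(np.int8),
    )
    meta = make_metadata({i: p for i, p in zip(ids, pops)})
    gmap = GeneticMap.from_records(
        [(f"s{j}", "c1", 2.0 * j + rng.uniform(0, 0.5)) for j in range(n_snps)]
    )
    model = CopyingModel.from_panel(donors, meta, rho=rho, theta=theta)
    return donors, meta, gmap, model


class TestModel:
    def test_watterson_default(self):
        theta = watterson_miscopy(10)
        assert 0 < theta < 0.5
        _, _, _, model = tiny_panel()
        default = CopyingModel.from_panel(
            GenotypeMatrix(model.donor_ids, model.snp_ids, model.donor_calls),
            make_metadata({d: int(p) for d, p in zip(model.donor_ids, model.donor_pops)}),
        )
        assert default.theta == pytest.approx(watterson_miscopy(4))

    def test_prior_normalised(self):
        _, _, _, model = tiny_panel(pops=(1, 1, 1, 2))
        pi = model.prior()
        assert pi.sum() == pytest.approx(1.0)
        # pop with 3 haplotypes splits its mass three ways
        assert pi[0] == pytest.approx(model.f[0] / 3)

    def test_single_pop_rejected(self):
        with pytest.raises(ValidationError):
            tiny_panel(pops=(1, 1, 1, 1))

    def test_invalid_rho(self):
        donors, meta, _, _ = tiny_panel()
        with pytest.raises(ValidationError):
            CopyingModel.from_panel(donors, meta, rho=0.0)


class TestForwardBackward:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_snps = int(rng.integers(3, 7))
        donors, meta, gmap, model = tiny_panel(seed=seed, n_snps=n_snps)
        model = model.with_f(np.array([0.3, 0.7]))
        rec = GenotypeMatrix(
            ["r0"], list(donors.snp_ids),
            rng.integers(0, 2, (1, n_snps)).astype(np.int8),
        )
        post = forward_backward(rec, model, gmap)
        pi = model.prior()
        stays = np.exp(-model.rho * np.diff(gmap.positions(post.snp_ids)))
        marg, loglik = oracles.hmm_posterior_brute(
            model.donor_calls[:, [donors.snp_ids.index(s) for s in post.snp_ids]],
            rec.calls[0, [donors.snp_ids.index(s) for s in post.snp_ids]],
            pi, stays, model.theta,
        )
        pop_marg = np.stack([marg[:, :2].sum(1), marg[:, 2:].sum(1)], axis=1)
        assert np.abs(post.probs[0] - pop_marg).max() < 1e-10
        assert post.loglik[0] == pytest.approx(loglik, abs=1e-10)

    def test_missing_recipient_site_uninformative(self):
        donors, meta, gmap, model = tiny_panel(seed=3)
        calls = np.array([[MISSING, MISSING, MISSING]], dtype=np.int8)
        rec = GenotypeMatrix(["r0"], list(donors.snp_ids), calls)
        post = forward_backward(rec, model, gmap)
        # all-missing recipient: posterior equals the prior by pop
        pi = model.prior()
        prior_by_pop = np.array([pi[:2].sum(), pi[2:].sum()])
        assert np.allclose(post.probs[0], prior_by_pop[None, :], atol=1e-12)

    def test_identity_recipient_high_posterior(self, small_donors):
        donors, gmap, meta = small_donors
        model = CopyingModel.from_panel(donors, meta, rho=0.05, theta=0.001)
        rec = GenotypeMatrix(["r0"], list(donors.snp_ids), donors.calls[[0]])
        post = forward_backward(rec, model, gmap)
        target = model.pop_ids.index(1)  # donor 0 belongs to pop 1
        frac = (post.probs[0, :, target] >= 0.99).mean()
        assert frac >= 0.95

    def test_rho_limit_posterior_constant(self):
        donors, meta, gmap, model = tiny_panel(seed=4, n_snps=5)
        from dataclasses import replace

        slow = replace(model, rho=1e-9)
        rng = np.random.default_rng(4)
        rec = GenotypeMatrix(
            ["r0"], list(donors.snp_ids), rng.integers(0, 2, (1, 5)).astype(np.int8)
        )
        post = forward_backward(rec, slow, gmap)
        assert np.abs(np.diff(post.probs[0], axis=0)).max() < 1e-6

    def test_normalisation(self, small_donors):
        donors, gmap, meta = small_donors
        model = CopyingModel.from_panel(donors, meta)
        rec = GenotypeMatrix(["r0"], list(donors.snp_ids), donors.calls[[5]])
        post = forward_backward(rec, model, gmap)
        assert np.abs(post.probs.sum(axis=2) - 1.0).max() < 1e-8


class TestEM:
    def test_exact_step_count_and_monotone(self):
        donors, meta, gmap, model = tiny_panel(seed=5, n_snps=6)
        rng = np.random.default_rng(5)
        rec = GenotypeMatrix(
            [f"r{i}" for i in range(4)], list(donors.snp_ids),
            rng.integers(0, 2, (4, 6)).astype(np.int8),
        )
        fitted, lls = fit_em(model, rec, gmap)
        assert len(lls) == model.n_em_steps == 20
        assert np.all(np.diff(lls) >= -1e-6 * np.abs(lls[:-1]))

    def test_monotone_with_theta_update(self):
        donors, meta, gmap, model = tiny_panel(seed=6, n_snps=6)
        rng = np.random.default_rng(6)
        rec = GenotypeMatrix(
            [f"r{i}" for i in range(4)], list(donors.snp_ids),
            rng.integers(0, 2, (4, 6)).astype(np.int8),
        )
        _, lls = fit_em(model, rec, gmap, update_theta=True)
        assert np.all(np.diff(lls) >= -1e-6 * np.abs(lls[:-1]))

    def test_pure_pop_recipients_recover_f(self, small_donors):
        donors, gmap, meta = small_donors
        rec, _ = simulate_mosaic_recipients(
            donors, gmap, meta, {1: 1.0}, 0.05, 8, seed=7, epsilon=0.0
        )
        model = CopyingModel.from_panel(donors, meta, n_em_steps=15)
        fitted, _ = fit_em(model, rec, gmap)
        assert fitted.f[fitted.pop_ids.index(1)] >= 0.95

    def test_fifty_fifty_recovery(self, small_donors):
        donors, gmap, meta = small_donors
        rec, _ = simulate_mosaic_recipients(
            donors, gmap, meta, {1: 0.5, 2: 0.5}, 1 / 30, 20, seed=8
        )
        model = CopyingModel.from_panel(donors, meta)
        fitted, _ = fit_em(model, rec, gmap)
        assert abs(fitted.f[fitted.pop_ids.index(1)] - 0.5) < 0.05
        assert abs(fitted.f[fitted.pop_ids.index(2)] - 0.5) < 0.05


class TestSampling:
    def test_deterministic_fixture_identical_paths(self):
        # one donor matches everywhere, all others mismatch everywhere;
        # with a tiny theta every sampled path is the matching donor
        m = 5
        ids = ["d0", "d1", "d2", "d3"]
        calls = np.zeros((4, m), dtype=np.int8)
        calls[0] = 1
        donors = GenotypeMatrix(ids, [f"s{j}" for j in range(m)], calls)
        meta = make_metadata({"d0": 1, "d1": 1, "d2": 2, "d3": 2})
        gmap = GeneticMap.from_records([(f"s{j}", "c1", 2.0 * j) for j in range(m)])
        model = CopyingModel.from_panel(donors, meta, rho=0.1, theta=1e-9)
        rec = GenotypeMatrix(["r0"], list(donors.snp_ids), np.ones((1, m), dtype=np.int8))
        cons = sample_paintings(rec, model, gmap, n_replicates=50, seed=1)
        assert (cons.counts[0, :, cons.pop_ids.index(1)] == 50).all()

    def test_seed_determinism(self, small_donors):
        donors, gmap, meta = small_donors
        model = CopyingModel.from_panel(donors, meta)
        rec = GenotypeMatrix(["r0"], list(donors.snp_ids), donors.calls[[3]])
        c1 = sample_paintings(rec, model, gmap, n_replicates=20, seed=5)
        c2 = sample_paintings(rec, model, gmap, n_replicates=20, seed=5)
        assert np.array_equal(c1.counts, c2.counts)

    def test_empirical_frequencies_converge_to_posterior(self):
        donors, meta, gmap, model = tiny_panel(seed=10, n_snps=5)
        model = model.with_f(np.array([0.4, 0.6]))
        rng = np.random.default_rng(10)
        rec = GenotypeMatrix(
            ["r0"], list(donors.snp_ids), rng.integers(0, 2, (1, 5)).astype(np.int8)
        )
        post = forward_backward(rec, model, gmap)
        cons = sample_paintings(rec, model, gmap, n_replicates=1000, seed=11)
        emp = cons.counts[0] / 1000.0
        tv = 0.5 * np.abs(emp - post.probs[0]).sum(axis=1)
        assert tv.max() < 0.05

    def test_counts_sum_to_replicates(self, small_donors):
        donors, gmap, meta = small_donors
        model = CopyingModel.from_panel(donors, meta)
        rec = GenotypeMatrix(["r0"], list(donors.snp_ids), donors.calls[[40]])
        cons = sample_paintings(rec, model, gmap, n_replicates=17, seed=2)
        assert (cons.counts.sum(axis=2) == 17).all()


class TestConsensus:
    @staticmethod
    def counts_fixture(count_rows, pops):
        counts = np.array([count_rows], dtype=np.int32)
        m = counts.shape[1]
        return PaintingConsensus(
            recipient_ids=["r0"],
            snp_ids=[f"s{j}" for j in range(m)],
            chrom=np.array(["c1"] * m),
            cm=np.arange(m, dtype=float),
            pop_ids=list(pops),
            counts=counts,
            n_replicates=int(counts[0, 0].sum()),
        )

    def test_modal_majority(self):
        cons = self.counts_fixture([[40, 60]], pops=[8, 22])
        modal, tie = cons.modal()
        assert modal[0, 0] == 22 and not tie[0, 0]

    def test_tie_breaks_to_smallest_id_flagged(self):
        cons = self.counts_fixture([[50, 50]], pops=[8, 22])
        modal, tie = cons.modal()
        assert modal[0, 0] == 8 and tie[0, 0]

    def test_support(self):
        cons = self.counts_fixture([[25, 75]], pops=[1, 2])
        assert cons.support[0, 0] == pytest.approx(0.75)


class TestSummaries:
    def test_single_pop_recipient(self):
        cons = TestConsensus.counts_fixture([[0, 10], [0, 10], [0, 10]], pops=[1, 22])
        summ = summarize_ancestry(cons)
        assert summ.recipient_proportions.loc["r0", 22] == pytest.approx(1.0)
        assert summ.recipient_proportions.loc["r0", 1] == pytest.approx(0.0)

    def test_group_proportions_by_period(self, small_donors):
        donors, gmap, meta = small_donors
        rec, truth = simulate_mosaic_recipients(
            donors, gmap, meta, {1: 0.5, 2: 0.5}, 0.05, 6, seed=12
        )
        model = CopyingModel.from_panel(donors, meta)
        cons = sample_paintings(rec, model, gmap, n_replicates=10, seed=3)
        rmeta = make_metadata(
            recipients=[(r, 1900 + 30 * (i % 3), "NSW") for i, r in enumerate(rec.sample_ids)]
        )
        from haplopaint.data_model import assign_periods

        rmeta = assign_periods(rmeta)
        summ = summarize_ancestry(cons, rmeta, group_by="period")
        assert np.allclose(summ.group_proportions.sum(axis=1), 1.0)
        for prof in summ.locus_profiles.values():
            assert np.allclose(prof.sum(axis=1), 1.0)


class TestCleanerPainting:
    def test_empty_exclusion_identical(self, small_donors):
        donors, gmap, meta = small_donors
        rec, _ = simulate_mosaic_recipients(
            donors, gmap, meta, {1: 0.6, 2: 0.4}, 0.05, 4, seed=13
        )
        std = paint_panel(donors, rec, gmap, meta, n_em_steps=3, n_replicates=10, seed=4)
        clean = cleaner_painting(
            donors, rec, gmap, meta, exclude_pops=[], n_em_steps=3, n_replicates=10, seed=4
        )
        assert np.array_equal(std.consensus.counts, clean.consensus.counts)

    def test_excluding_idle_pop_barely_changes_summaries(self, small_donors):
        donors, gmap, meta = small_donors
        rec, _ = simulate_mosaic_recipients(
            donors, gmap, meta, {1: 0.5, 2: 0.5}, 0.05, 10, seed=14, epsilon=0.0
        )
        std = paint_panel(donors, rec, gmap, meta, n_em_steps=8, n_replicates=40, seed=5)
        clean = cleaner_painting(
            donors, rec, gmap, meta, exclude_pops=[4],
            n_em_steps=8, n_replicates=40, seed=5,
        )
        p_std = summarize_ancestry(std.consensus).recipient_proportions.mean()
        p_clean = summarize_ancestry(clean.consensus).recipient_proportions.mean()
        for pop in (1, 2, 3):
            assert abs(p_std[pop] - p_clean[pop]) <= 0.02

    def test_excluded_major_donor_reassigns_to_relative(self):
        # pop 3 is a noisy copy of pop 1; pop 2 is unrelated.  Excluding the
        # true donor (pop 1) must push mass to pop 3, not pop 2.
        rng = np.random.default_rng(15)
        m = 300
        pop1 = rng.integers(0, 2, (10, m)).astype(np.int8)
        noise = rng.random((10, m)) < 0.03
        pop3 = np.where(noise, 1 - pop1, pop1).astype(np.int8)
        pop2 = rng.integers(0, 2, (10, m)).astype(np.int8)
        ids = (
            [f"a{i}" for i in range(10)]
            + [f"b{i}" for i in range(10)]
            + [f"c{i}" for i in range(10)]
        )
        donors = GenotypeMatrix(
            ids, [f"s{j}" for j in range(m)], np.concatenate([pop1, pop2, pop3])
        )
        meta = make_metadata(
            {**{f"a{i}": 1 for i in range(10)},
             **{f"b{i}": 2 for i in range(10)},
             **{f"c{i}": 3 for i in range(10)}}
        )
        gmap = GeneticMap.from_records(
            [(f"s{j}", "c1", float(j)) for j in range(m)]
        )
        rec = GenotypeMatrix(["r0", "r1"], donors.snp_ids, pop1[[0, 5]].copy())
        clean = cleaner_painting(
            donors, rec, gmap, meta, exclude_pops=[1],
            n_em_steps=6, n_replicates=30, seed=6,
        )
        props = summarize_ancestry(clean.consensus).recipient_proportions.mean()
        assert props[3] > props[2]

    def test_too_few_remaining_pops_rejected(self, small_donors):
        donors, gmap, meta = small_donors
        with pytest.raises(ValidationError):
            cleaner_painting(donors, donors, gmap, meta, exclude_pops=[1, 2, 3])


class TestDeviantRegions:
    @staticmethod
    def profile(focal_series, other_pops=(22, 12)):
        m = len(focal_series)
        focal = np.asarray(focal_series, dtype=float)
        rest = (1.0 - focal) / (len(other_pops) - 1)
        data = {other_pops[0]: focal}
        for p in other_pops[1:]:
            data[p] = rest
        return pd.DataFrame(data, index=[f"s{j}" for j in range(m)])

    def test_no_regions_when_dominant_everywhere(self):
        prof = self.profile(np.ones(20))
        regs = detect_deviant_regions(
            prof, ["c1"] * 20, np.arange(20.0), focal_subpop=22
        )
        assert regs == []

    def test_run_length_rule(self):
        focal = np.ones(20)
        focal[2:4] = 0.1  # run of 2: below min_snps
        focal[8:13] = 0.1  # run of 5: reported
        prof = self.profile(focal)
        regs = detect_deviant_regions(
            prof, ["c1"] * 20, np.arange(20.0), focal_subpop=22, min_snps=3
        )
        assert len(regs) == 1
        assert regs[0].start_snp == "s8" and regs[0].end_snp == "s12"
        assert regs[0].n_snps == 5
        assert 12 in regs[0].dominant_subpops

    def test_runs_do_not_cross_chromosomes(self):
        focal = np.full(10, 0.1)
        chrom = ["c1"] * 5 + ["c2"] * 5
        prof = self.profile(focal)
        regs = detect_deviant_regions(
            prof, chrom, np.arange(10.0), focal_subpop=22, min_snps=3
        )
        assert len(regs) == 2
        assert {r.chrom for r in regs} == {"c1", "c2"}

    def test_planted_block_recovered(self, small_donors):
        donors, gmap, meta = small_donors
        # recipients copy pop 1 everywhere except a 30 cM block from pop 2
        pops = meta.subpop_of(donors.sample_ids)
        idx1 = np.where(pops == 1)[0]
        idx2 = np.where(pops == 2)[0]
        order = gmap.order_matrix(donors)
        chrom, ids = order[0]
        cm = gmap.positions(ids)
        block = (cm >= 40) & (cm <= 70)
        rng = np.random.default_rng(16)
        n_rec = 12
        calls = donors.calls[rng.choice(idx1, n_rec)].copy()
        cols = donors.snp_index(ids)
        donor2 = donors.calls[rng.choice(idx2, n_rec)]
        calls[:, cols[block]] = donor2[:, cols[block]]
        rec = GenotypeMatrix([f"r{i}" for i in range(n_rec)], donors.snp_ids, calls)
        res = paint_panel(donors, rec, gmap, meta, n_em_steps=8, n_replicates=40, seed=7)
        summ = summarize_ancestry(res.consensus)
        modal, _ = res.consensus.modal()
        prof = pd.DataFrame(
            np.stack([(modal == p).mean(axis=0) for p in res.consensus.pop_ids], axis=1),
            index=res.consensus.snp_ids,
            columns=res.consensus.pop_ids,
        )
        regs = detect_deviant_regions(
            prof, res.consensus.chrom, res.consensus.cm, focal_subpop=1
        )
        in_block = [r for r in regs if r.chrom == chrom and r.end_cm >= 40 and r.start_cm <= 70]
        assert len(in_block) >= 1
        assert any(2 in r.dominant_subpops for r in in_block)


class TestEndToEndAccuracyOrdering:
    def test_accuracy_monotone_in_differentiation(self):
        from haplopaint.synthetic_data import DonorSimConfig, simulate_donor_pops

        accs = {}
        for fst in (0.05, 0.3):
            scores = []
            for seed in range(3):
                g, gmap, meta = simulate_donor_pops(
                    DonorSimConfig(
                        n_subpops=3, fst=fst, n_snps=400, n_chromosomes=2,
                        map_length_cm=100.0, n_samples=20, seed=100 + seed,
                    )
                )
                rec, truth = simulate_mosaic_recipients(
                    g, gmap, meta, {1: 0.5, 2: 0.5}, 1 / 30, 8, seed=seed
                )
                res = paint_panel(g, rec, gmap, meta, n_em_steps=6, n_replicates=30, seed=seed)
                modal, _ = res.consensus.modal()
                lab = truth.labels_at_snps(gmap, res.consensus.snp_ids).to_numpy()
                scores.append((modal == lab).mean())
            accs[fst] = np.mean(scores)
        assert accs[0.3] >= accs[0.05]
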