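"""The updating machinery: external posterior, current MME, exact equivalence."""

import numpy as np
import pytest
import scipy.sparse as sp

import tierblup as tb
from tierblup import mme
from tierblup.relatedness import block


def _equivalence(pop, common, kinv_mode="pedigree", grm=None, corrupt_eaa=False):
    data_e, data_c = pop.data_split()
    cfg = pop.config
    ext = tb.run_external(pop.ped, pop.part, data_e, cfg.sigma_u, cfg.sigma_e,
                          common_effect_names=common, kinv_mode=kinv_mode, grm=grm)
    if corrupt_eaa:
        E = ext.Eaa.tolil()
        E[0, 0] += 0.05
        ext.Eaa = E.tocsr()
    upd_sys = tb.build_update_mme(ext, pop.ped, pop.part, data_c)
    upd_res = tb.solve(upd_sys)
    joint = tb.merge_designs(data_e, data_c, common)
    jsys, jres = tb.run_joint(pop.ped, joint, cfg.sigma_u, cfg.sigma_e,
                              kinv_mode=kinv_mode, grm=grm)
    return tb.verify_equivalence(jsys, jres, upd_sys, upd_res, pop.part), ext, upd_sys


def _grm_for(pop, n_genotyped, n_markers=120, seed=9):
    rng = np.random.default_rng(seed)
    gids = pop.genotypes.index.tolist()[-n_genotyped:] if pop.genotypes is not None \
        else [l for l, t in pop.tiers.items() if t == "nucleus"][:n_genotyped]
    if pop.genotypes is not None:
        M = pop.genotypes.loc[gids].to_numpy(float)
    else:
        M = rng.binomial(2, 0.5, size=(n_genotyped, n_markers)).astype(float)
    A = tb.build_A_tabular(pop.ped)
    gidx = [pop.ped.index[i] for i in gids]
    return tb.build_grm(M, gids, A_gg=A[np.ix_(gidx, gidx)])


class TestRunExternal:
    def test_no_records_posterior_is_prior_marginal(self, small_pop):
        pop = small_pop
        empty = tb.PhenotypeData(y=np.zeros(0), X=np.zeros((0, 0)),
                                 x_names=[], animals=[])
        ext = tb.run_external(pop.ped, pop.part, empty, 0.3, 0.7)
        assert np.allclose(ext.mean_ua, 0.0)
        A = tb.build_A_tabular(pop.ped)
        Aaa = A[np.ix_(pop.part.a_idx, pop.part.a_idx)]
        assert np.max(np.abs(ext.C - Aaa * 0.3)) < 1e-9

    def test_C_equals_dense_inverse_block(self, small_pop_cov):
        pop = small_pop_cov
        data_e, _ = pop.data_split()
        ext = tb.run_external(pop.ped, pop.part, data_e, 0.3, 0.7,
                              common_effect_names=["covariate"])
        # rebuild the external system densely and invert
        from tierblup.pedigree import extract_subpedigree
        ped_e = extract_subpedigree(
            pop.ped, [pop.ped.labels[i] for i in pop.part.e_idx], "clip-parents")
        Einv = tb.build_A_inverse(ped_e)
        rows = np.arange(len(data_e.animals))
        cols = [ped_e.index[a] for a in data_e.animals]
        Z = sp.csr_matrix((np.ones(rows.size), (rows, cols)),
                          shape=(rows.size, ped_e.n))
        sys = tb.build_joint_mme(data_e.y, data_e.X, Z, Einv, 0.3, 0.7,
                                 fixed_names=data_e.x_names)
        inv = np.linalg.inv(sys.lhs.toarray())
        nf = len(data_e.x_names)
        coords = [data_e.x_names.index("covariate")] + \
            [nf + ped_e.index[a] for a in ext.a_ids]
        assert np.max(np.abs(ext.C - inv[np.ix_(coords, coords)])) < 1e-8

    def test_gibbs_C_close_to_direct(self, small_pop):
        pop = small_pop
        data_e, _ = pop.data_split()
        direct = tb.run_external(pop.ped, pop.part, data_e, 0.3, 0.7)
        est = tb.run_external(pop.ped, pop.part, data_e, 0.3, 0.7,
                              gibbs={"n_iter": 4000, "burn_in": 500, "seed": 2})
        rel = np.linalg.norm(est.C - direct.C) / np.linalg.norm(direct.C)
        assert rel < 0.25  # loose: short chain; the tight check runs at 100k

    def test_records_outside_external_set_rejected(self, small_pop):
        pop = small_pop
        c_lab = pop.part.labels("c")[0]
        bad = tb.PhenotypeData(y=[1.0], X=np.ones((1, 1)), x_names=["mu"],
                               animals=[c_lab])
        with pytest.raises(tb.PedigreeError, match="external"):
            tb.run_external(pop.ped, pop.part, bad, 0.3, 0.7)


class TestInvertPosterior:
    def test_identity_C(self):
        ext = tb.ExternalPosterior(
            a_ids=["a1", "a2"], common_effect_names=["h"],
            mean_beta=[0.0], mean_ua=[0.0, 0.0], C=np.eye(3),
            Eaa=sp.eye(2, format="csr"), sigma_u=1.0, sigma_e=1.0,
        )
        prec = tb.invert_posterior(ext)
        assert np.allclose(prec["bb"], [[1.0]])
        assert np.allclose(prec["aa"], np.eye(2))
        assert np.allclose(prec["ba"], 0.0)

    def test_block_inverse_identity(self):
        rng = np.random.default_rng(8)
        L = rng.standard_normal((4, 4))
        C = L @ L.T + 4 * np.eye(4)
        ext = tb.ExternalPosterior(
            a_ids=["a1", "a2", "a3"], common_effect_names=["h"],
            mean_beta=[0.0], mean_ua=np.zeros(3), C=C,
            Eaa=sp.eye(3, format="csr"), sigma_u=1.0, sigma_e=1.0,
        )
        p = tb.invert_posterior(ext)
        # C^aa − C^aβ (C^ββ)⁻¹ C^βa = (marginal C_aa)⁻¹
        lhs = p["aa"] - p["ab"] @ np.linalg.inv(p["bb"]) @ p["ba"]
        assert np.allclose(lhs, np.linalg.inv(C[1:, 1:]))

    def test_no_common_effects_is_plain_pev_inverse(self):
        C = np.array([[2.0, 0.5], [0.5, 1.0]])
        ext = tb.ExternalPosterior(
            a_ids=["a1", "a2"], common_effect_names=[],
            mean_beta=[], mean_ua=[0.0, 0.0], C=C,
            Eaa=sp.eye(2, format="csr"), sigma_u=1.0, sigma_e=1.0,
        )
        p = tb.invert_posterior(ext)
        assert p["bb"].size == 0
        assert np.allclose(p["aa"], np.linalg.inv(C))


class TestBuildUpdateMME:
    def test_no_current_records_fixed_point(self, small_pop):
        pop = small_pop
        data_e, _ = pop.data_split()
        ext = tb.run_external(pop.ped, pop.part, data_e, 0.3, 0.7)
        empty = tb.PhenotypeData(y=np.zeros(0), X=np.zeros((0, 0)),
                                 x_names=[], animals=[])
        sys = tb.build_update_mme(ext, pop.ped, pop.part, empty)
        res = tb.solve(sys)
        ua = res.block_solution("u_a")
        uc = res.block_solution("u_c")
        assert np.max(np.abs(ua - ext.mean_ua)) < 1e-9
        # u_c is the conditional-mean propagation A_ca A_aa^-1 u_a
        A = tb.build_A_tabular(pop.ped)
        Aca = A[np.ix_(pop.part.c_idx, pop.part.a_idx)]
        Aaa = A[np.ix_(pop.part.a_idx, pop.part.a_idx)]
        assert np.max(np.abs(uc - Aca @ np.linalg.solve(Aaa, ext.mean_ua))) < 1e-8

    def test_lhs_aa_block_is_quadratic_form_identity(self, small_pop):
        pop = small_pop
        data_e, data_c = pop.data_split()
        ext = tb.run_external(pop.ped, pop.part, data_e, 0.3, 0.7)
        sys = tb.build_update_mme(ext, pop.ped, pop.part, data_c)
        Finv = tb.build_A_inverse(pop.ped)
        Fac = block(Finv, pop.part.a_idx, pop.part.c_idx).toarray()
        Fcc = block(Finv, pop.part.c_idx, pop.part.c_idx).toarray()
        prec = tb.invert_posterior(ext)
        expect = prec["aa"] + (Fac @ np.linalg.inv(Fcc) @ Fac.T) / 0.3
        got = sys.lhs.toarray()[np.ix_(sys.blocks["u_a"], sys.blocks["u_a"])]
        assert np.max(np.abs(got - expect)) < 1e-8

    def test_records_on_parents_rejected(self, small_pop):
        pop = small_pop
        data_e, data_c = pop.data_split()
        ext = tb.run_external(pop.ped, pop.part, data_e, 0.3, 0.7)
        a_lab = pop.part.labels("a")[0]
        bad = tb.PhenotypeData(
            y=np.append(data_c.y, 1.0),
            X=np.vstack([data_c.X, np.ones((1, data_c.X.shape[1]))]),
            x_names=data_c.x_names,
            animals=data_c.animals + [a_lab],
        )
        with pytest.raises(tb.PedigreeError, match="current"):
            tb.build_update_mme(ext, pop.ped, pop.part, bad)


class TestEquivalence:
    def test_pblup_exact(self, small_pop):
        rep, _, _ = _equivalence(small_pop, [])
        assert rep.max_ebv_diff < 1e-8
        assert rep.max_pev_diff < 1e-8
        assert rep.passed

    def test_pblup_with_common_fixed_effect(self, small_pop_cov):
        rep, _, _ = _equivalence(small_pop_cov, ["covariate"])
        assert rep.max_ebv_diff < 1e-8
        assert rep.max_beta_diff < 1e-8
        assert rep.max_pev_diff < 1e-8

    def test_ssgblup_exact_without_ancestor_genotypes(self, small_pop):
        grm = _grm_for(small_pop, 12)
        rep, _, _ = _equivalence(small_pop, [], kinv_mode="single-step", grm=grm)
        assert rep.max_ebv_diff < 1e-8
        assert rep.max_pev_diff < 1e-8

    def test_corrupting_eaa_breaks_equivalence(self, small_pop):
        rep, _, _ = _equivalence(small_pop, [], corrupt_eaa=True)
        assert not rep.passed

    def test_equation_count_bookkeeping(self, small_pop):
        # order(external) + order(current) − order(joint) = |a| + |common|
        pop = small_pop
        data_e, data_c = pop.data_split()
        ext = tb.run_external(pop.ped, pop.part, data_e, 0.3, 0.7)
        upd = tb.build_update_mme(ext, pop.ped, pop.part, data_c)
        joint = tb.merge_designs(data_e, data_c, [])
        jsys, _ = tb.run_joint(pop.ped, joint, 0.3, 0.7)
        n_ext = len(data_e.x_names) + len(pop.part.e_idx)
        overlap = (n_ext + upd.n) - jsys.n
        assert overlap == len(pop.part.a_idx) + 0
        assert overlap >= 0


class TestBayesianEqualsAbsorption:
    def test_update_system_matches_absorbed_joint(self, small_pop):
        """With no fixed effects anywhere, the updating MME equals the joint
        MME with distant ancestors absorbed and the external-PEV inverse
        substituted — matrix by matrix."""
        pop = small_pop
        data_e, data_c = pop.data_split()
        # strip fixed effects entirely
        strip = lambda d: tb.PhenotypeData(
            y=d.y - d.y.mean(), X=np.zeros((d.y.size, 0)), x_names=[],
            animals=d.animals)
        de, dc = strip(data_e), strip(data_c)
        ext = tb.run_external(pop.ped, pop.part, de, 0.3, 0.7)
        upd = tb.build_update_mme(ext, pop.ped, pop.part, dc)

        joint = tb.merge_designs(de, dc, [])
        Finv = tb.build_A_inverse(pop.ped)
        rows = np.arange(len(joint.animals))
        cols = [pop.ped.index[a] for a in joint.animals]
        Z = sp.csr_matrix((np.ones(rows.size), (rows, cols)),
                          shape=(rows.size, pop.ped.n))
        jsys = tb.build_joint_mme(joint.y, np.zeros((rows.size, 0)), Z, Finv,
                                  0.3, 0.7, animal_labels=pop.ped.labels)
        # split the animal block into d and a∪c, absorb d
        split = mme.MMESystem(
            lhs=jsys.lhs, rhs=jsys.rhs,
            blocks={"u_d": pop.part.d_idx,
                    "u_ac": np.concatenate([pop.part.a_idx, pop.part.c_idx])},
            sigma_u=0.3, sigma_e=0.7,
        )
        red = tb.absorb(split, "u_d")
        assert np.max(np.abs(red.lhs.toarray() - upd.lhs.toarray())) < 1e-9
        assert np.max(np.abs(red.rhs - upd.rhs)) < 1e-9


class TestPosteriorPackageIO:
    def test_round_trip(self, tmp_path, small_pop_cov):
        from tierblup import io as tio
        pop = small_pop_cov
        data_e, _ = pop.data_split()
        ext = tb.run_external(pop.ped, pop.part, data_e, 0.3, 0.7,
                              common_effect_names=["covariate"])
        tio.write_posterior(ext, tmp_path / "post")
        back = tio.read_posterior(tmp_path / "post")
        assert back.a_ids == ext.a_ids
        assert back.common_effect_names == ext.common_effect_names
        assert np.allclose(back.mean_beta, ext.mean_beta)
        assert np.allclose(back.mean_ua, ext.mean_ua)
        assert np.max(np.abs(back.C - ext.C)) < 1e-9
        assert np.max(np.abs((back.Eaa - ext.Eaa).toarray())) < 1e-12
        assert back.sigma_u == ext.sigma_u
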