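import numpy as np
import pytest

from plastidsel.codon_core import get_code
from plastidsel.codon_ml import (INTERNAL, CodonModelParams, PatternAlignment,
                                 _BranchPropagator, build_gy94_rate_matrix,
                                 f3x4_frequencies, fit_branch_model,
                                 lrt_omega_equals_one, sense_codons,
                                 transition_matrix, tree_log_likelihood)
from plastidsel.divergence import CodonAlignment

from oracles import expm_transition, pruning_oracle_4taxon

CODE = get_code(11)
SENSE = sense_codons(CODE)
SPECIES = ("Cam", "Tca", "Han", "Nta")


def _uniform_pi():
    return np.full(61, 1.0 / 61)


def _params(kappa=2.0, omega=0.4, t=0.1, pi=None):
    branches = SPECIES + (INTERNAL,)
    return CodonModelParams(
        kappa=kappa,
        omega={b: omega for b in branches},
        branch_lengths={b: t for b in branches},
        pi=_uniform_pi() if pi is None else pi,
        species=SPECIES,
    )


# ---------------------------------------------------------------------------
# F3x4


def test_f3x4_uniform_composition_gives_uniform_pi():
    # all 61 sense codons once -> near-uniform base usage; with zero
    # pseudocount and exactly uniform per-position composition pi_i = 1/61
    seq = "".join(
        a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
    )
    aln = CodonAlignment("x", {"s": seq})
    pi = f3x4_frequencies(aln, CODE, pseudocount=0.0)
    assert pi == pytest.approx(np.full(61, 1 / 61), abs=1e-12)
    assert pi.sum() == pytest.approx(1.0)


def test_f3x4_position_restriction_zeroes_codons():
    aln = CodonAlignment("x", {"s": "TTTTTCTTATTG" * 3})
    pi = f3x4_frequencies(aln, CODE, pseudocount=0.0)
    codon_of = dict(zip(SENSE, pi))
    assert all(codon_of[c] == 0 for c in SENSE if not c.startswith("T"))
    # pseudocounts lift the structural zeros
    pi_pc = f3x4_frequencies(aln, CODE, pseudocount=0.5)
    assert (pi_pc > 0).all() and pi_pc.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# rate matrix and propagator


def test_rate_matrix_rows_sum_to_zero_and_reversibility():
    pi = f3x4_frequencies(
        CodonAlignment("x", {"s": "ATGGCTAAACCCGGGTTTAGA"}), CODE)
    Q = build_gy94_rate_matrix(2.3, 0.7, pi, CODE)
    assert np.abs(Q.sum(axis=1)).max() < 1e-10
    balance = pi[:, None] * Q - (pi[:, None] * Q).T
    assert np.abs(balance).max() < 1e-12
    # unit expected rate at equilibrium
    assert -float(pi @ np.diag(Q)) == pytest.approx(1.0)


def test_omega_zero_removes_nonsynonymous_rates():
    Q = build_gy94_rate_matrix(2.0, 0.0, _uniform_pi(), CODE)
    aa = [CODE.translate(c) for c in SENSE]
    for i in range(61):
        for j in range(61):
            if i != j and aa[i] != aa[j]:
                assert Q[i, j] == 0.0


def test_transition_matrix_properties():
    pi = _uniform_pi()
    P0 = transition_matrix(2.0, 0.4, pi, 0.0, CODE)
    assert P0 == pytest.approx(np.eye(61), abs=1e-10)
    for t in (0.01, 0.5, 10.0):
        P = transition_matrix(2.0, 0.4, pi, t, CODE)
        assert P.sum(axis=1) == pytest.approx(np.ones(61), abs=1e-10)
        # pi is stationary
        assert pi @ P == pytest.approx(pi, abs=1e-8)


def test_transition_matrix_matches_pade_expm():
    pi = f3x4_frequencies(CodonAlignment("x", {"s": "ATGGCTAAACCCGGGTTTAGA"}), CODE)
    Q = build_gy94_rate_matrix(3.0, 0.2, pi, CODE)
    ours = _BranchPropagator(3.0, 0.2, pi, CODE).transition_matrix(0.3)
    assert ours == pytest.approx(expm_transition(Q, 0.3), abs=1e-9)


# ---------------------------------------------------------------------------
# pruning likelihood


def test_two_leaf_reduction_identity():
    """With one branch of length t1+t2, L(x,y) = pi_x * P(x->y, t1+t2); the
    rooted two-branch pruning sum must equal it by reversibility."""
    pi = _uniform_pi()
    prop = _BranchPropagator(2.0, 0.4, pi, CODE)
    t1, t2 = 0.07, 0.18
    P1, P2, P12 = prop.transition_matrix(t1), prop.transition_matrix(t2), \
        prop.transition_matrix(t1 + t2)
    x, y = 5, 44
    rooted = float(np.sum(pi * P1[:, x] * P2[:, y]))
    assert rooted == pytest.approx(pi[x] * P12[x, y], rel=1e-10)


def test_all_identical_leaves_at_zero_length():
    codon = SENSE[10]
    aln = CodonAlignment("x", {sp: codon * 2 for sp in SPECIES})
    params = _params(t=1e-9)
    logL = tree_log_likelihood(aln, params, CODE)
    assert logL == pytest.approx(2 * np.log(params.pi[10]), abs=1e-4)


def test_pruning_matches_exhaustive_ancestral_sum():
    """Pruning equals brute-force summation over both internal nodes' 61
    states on a 3-codon alignment."""
    rng = np.random.default_rng(8)
    aln = CodonAlignment("x", {
        sp: "".join(SENSE[k] for k in rng.integers(0, 61, 3)) for sp in SPECIES
    })
    pi = f3x4_frequencies(aln, CODE)
    branches = SPECIES + (INTERNAL,)
    params = CodonModelParams(
        kappa=2.5,
        omega=dict(zip(branches, (0.2, 0.5, 1.0, 2.0, 0.8))),
        branch_lengths=dict(zip(branches, (0.05, 0.1, 0.2, 0.15, 0.08))),
        pi=pi, species=SPECIES,
    )
    logL = tree_log_likelihood(aln, params, CODE)

    data = PatternAlignment.from_alignment(aln, SPECIES, CODE)
    P = {b: _BranchPropagator(params.kappa, params.omega[b], pi, CODE)
         .transition_matrix(params.branch_lengths[b]) for b in branches}
    oracle = pruning_oracle_4taxon(
        data.states, data.counts, P["Cam"], P["Tca"], P["Han"], P["Nta"],
        P[INTERNAL], pi)
    assert logL == pytest.approx(oracle, abs=1e-9)


def test_loglik_invariant_to_site_order():
    rng = np.random.default_rng(9)
    cols = [tuple(SENSE[k] for k in rng.integers(0, 61, 4)) for _ in range(30)]

    def build(columns):
        return CodonAlignment("x", {
            sp: "".join(col[i] for col in columns)
            for i, sp in enumerate(SPECIES)})

    params = _params()
    assert tree_log_likelihood(build(cols), params, CODE) == pytest.approx(
        tree_log_likelihood(build(cols[::-1]), params, CODE), rel=1e-12)


def test_gapped_columns_dropped_listwise():
    aln = CodonAlignment("x", {
        "Cam": "ATG---GCT", "Tca": "ATGAAAGCT", "Han": "ATGAAAGCT", "Nta": "ATGAAAGCT"})
    data = PatternAlignment.from_alignment(aln, SPECIES, CODE)
    assert data.n_codons == 2


# ---------------------------------------------------------------------------
# fitting


@pytest.fixture(scope="module")
def simulated_gene():
    from plastidsel.simulate import SimConfig, simulate_gene_alignment

    cfg = SimConfig(n_genes=1, codons_per_gene=1500, omega_div=0.5, seed=21)
    rng = np.random.default_rng(21)
    aln, truth = simulate_gene_alignment(cfg, 0, rng)
    return aln, truth


def test_fit_is_deterministic(simulated_gene):
    aln, _ = simulated_gene
    fit1 = fit_branch_model(aln, SPECIES, CODE)
    fit2 = fit_branch_model(aln, SPECIES, CODE)
    assert fit1.log_likelihood == fit2.log_likelihood
    assert fit1.params.omega == fit2.params.omega


def test_constrained_fit_never_beats_free(simulated_gene):
    aln, _ = simulated_gene
    free = fit_branch_model(aln, SPECIES, CODE)
    constrained = fit_branch_model(
        aln, SPECIES, CODE,
        fixed_omega={b: 0.5 for b in SPECIES + (INTERNAL,)})
    assert constrained.log_likelihood <= free.log_likelihood + 1e-6


def test_lrt_statistic_near_zero_when_estimate_is_one():
    """If the free estimate on the tested branch is ~1, constraining to 1
    changes essentially nothing."""
    from plastidsel.simulate import SimConfig, simulate_gene_alignment

    cfg = SimConfig(n_genes=1, codons_per_gene=800, omega_div=1.0, seed=33)
    rng = np.random.default_rng(33)
    aln, _ = simulate_gene_alignment(cfg, 0, rng)
    free = fit_branch_model(aln, SPECIES, CODE)
    lrt = lrt_omega_equals_one(aln, SPECIES, "Cam", CODE, free_fit=free)
    assert lrt.statistic >= 0
    if abs(free.params.omega["Cam"] - 1.0) < 0.05:
        assert lrt.statistic < 0.5
    assert 0 <= lrt.p_value <= 1
    assert lrt.p_bonferroni == pytest.approx(min(1.0, lrt.p_value * 17))


def test_lrt_detects_strong_positive_selection():
    from plastidsel.simulate import SimConfig, simulate_gene_alignment

    omega = {b: 0.4 for b in SPECIES + (INTERNAL,)}
    omega["Cam"] = 5.0
    cfg = SimConfig(n_genes=1, codons_per_gene=2000, omega_div=[omega], seed=55)
    rng = np.random.default_rng(55)
    aln, _ = simulate_gene_alignment(cfg, 0, rng)
    lrt = lrt_omega_equals_one(aln, SPECIES, "Cam", CODE)
    assert lrt.free_omega > 1.0
    assert lrt.statistic > 0 and lrt.p_value < 0.05


def test_unknown_branch_rejected(simulated_gene):
    aln, _ = simulated_gene
    with pytest.raises(KeyError):
        lrt_omega_equals_one(aln, SPECIES, "nope", CODE)
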