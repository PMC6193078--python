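"""Logistic clonal growth, the alloreactivity tensor, and response risk."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allodyn import (
    AntigenParams,
    CloneParams,
    CytokineField,
    GvhdProbabilityInputs,
    SimulationConfig,
    build_allo_tensor,
    compose_r,
    cytokine_amplified_step,
    cytokine_net,
    gvhd_probability,
    ic50_to_affinity,
    k_prime,
    logistic_step,
    transform_repertoire,
)


def _antigen(b=0.02, p=1.0, c=1.0, aid="a"):
    return AntigenParams(antigen_id=aid, b_affinity=b, expression=p,
                         scavenging=c)


def _clone(z=0.5, k=1000.0, n0=1.0, cp=1, s2=1, cid="c"):
    return CloneParams(clone_id=cid, z_affinity=z, carrying_capacity=k,
                       n0=n0, cp=cp, s2=s2)


def iterate(antigen, clone, r, t_max, step=logistic_step, **kw):
    n = clone.n0
    out = [n]
    for t in range(1, t_max + 1):
        n = step(n, t, antigen, clone, r, **kw)
        out.append(n)
    return np.array(out)


class TestAffinityConversion:
    @pytest.mark.parametrize("ic50,b", [(50.0, 0.02), (1.0, 1.0),
                                        (40.2, 1 / 40.2)])
    def test_reciprocal(self, ic50, b):
        assert ic50_to_affinity(ic50) == pytest.approx(b)

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            ic50_to_affinity(0.0)


class TestSignalComposition:
    def test_gates(self):
        assert compose_r(1, 1, 3.5) == 3.5        # full signal passes Ck
        assert compose_r(0, 1, 3.5) == 0          # PD1 engaged
        assert compose_r(1, 0, 3.5) == 0          # CTLA4 instead of CD28

    def test_cytokine_net_signed_sum(self):
        fld = CytokineField(entries=((2.0, 1.0, 1), (1.0, 1.0, -1)))
        assert cytokine_net(fld) == 1.0           # IL12 drive minus IL10
        assert cytokine_net(CytokineField(entries=((0.0, 0.0, 1),))) == 0.0

    def test_receptor_level_override_and_mismatch(self):
        fld = CytokineField(entries=((2.0, 1.0, 1),))
        assert cytokine_net(fld, receptor_levels=[3.0]) == 6.0
        with pytest.raises(ValueError):
            cytokine_net(fld, receptor_levels=[1.0, 2.0])

    def test_suppressive_field_decays_clone(self):
        fld = CytokineField(entries=((1.0, 1.0, -1),))
        r = compose_r(1, 1, cytokine_net(fld))
        assert r < 0
        traj = iterate(_antigen(), _clone(n0=1.0), r, 500)
        assert traj[-1] < traj[0]
        assert traj[-1] < 1e-3        # decays toward extinction


class TestLogisticStep:
    def test_growth_arrest_r_zero_exact(self):
        antigen, clone = _antigen(), _clone(n0=1.0)
        traj = iterate(antigen, clone, r=0.0, t_max=50)
        assert (traj == 1.0).all()

    def test_converges_to_k_prime(self):
        antigen, clone = _antigen(), _clone()
        kp = k_prime(antigen, clone)     # 1*1*1000*0.02*0.5 = 10
        assert kp == 10.0
        traj = iterate(antigen, clone, r=1.0, t_max=10_000)
        assert abs(traj[-1] - kp) / kp < 1e-6

    def test_first_step_closed_form(self):
        # K'=10, N0=Nprev=1, r=1, t=1: N1 = 10/(9 e^{-0.02} + 1)
        n1 = logistic_step(1.0, 1, _antigen(), _clone(), r=1.0)
        assert n1 == pytest.approx(10 / (9 * math.exp(-0.02) + 1))

    def test_class_ii_scavenging_reduces_steady_state(self):
        clone = _clone()
        full = iterate(_antigen(c=1.0), clone, 1.0, 2000)
        scavenged = iterate(_antigen(c=0.4), clone, 1.0, 2000)
        assert scavenged[-1] < full[-1]
        assert scavenged[-1] == pytest.approx(0.4 * full[-1], rel=1e-5)

    def test_scavenging_one_recovers_class_i_equation(self):
        traj_i = iterate(_antigen(c=1.0), _clone(), 1.0, 100)
        # c = 1 is the class I special case: same parameters, same path
        antigen_ii = AntigenParams(antigen_id="a", b_affinity=0.02,
                                   expression=1.0, scavenging=1.0)
        traj_ii = iterate(antigen_ii, _clone(), 1.0, 100)
        assert (traj_i == traj_ii).all()

    def test_overcapacity_start_clamped_with_warning(self):
        antigen, clone = _antigen(), _clone()
        kp = k_prime(antigen, clone)
        with pytest.warns(UserWarning, match="clamping"):
            n = logistic_step(kp + math.exp(1 * 0.02) + 1, 1, antigen,
                              clone, r=-1.0)
        assert n == kp * clone.n0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=st.floats(0.1, 100), c=st.floats(0.1, 1.0),
           k=st.floats(10, 1e4), b=st.floats(2e-3, 1.0),
           z=st.floats(2e-3, 1.0))
    def test_steady_state_linear_in_each_factor(self, p, c, k, b, z):
        """Doubling any one of P, c, K, B, Z doubles the steady state."""
        base = k_prime(AntigenParams("a", b, p, c), _clone(z=z, k=k))
        assert k_prime(AntigenParams("a", b, 2 * p, c),
                       _clone(z=z, k=k)) == pytest.approx(2 * base)
        assert k_prime(AntigenParams("a", 2 * b, p, c),
                       _clone(z=z, k=k)) == pytest.approx(2 * base)
        assert k_prime(AntigenParams("a", b, p, c),
                       _clone(z=2 * z, k=k)) == pytest.approx(2 * base)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(b=st.floats(2e-3, 1.0), z=st.floats(2e-3, 1.0),
           p=st.floats(0.5, 50), r=st.floats(0.5, 3.0))
    def test_convergence_over_random_parameters(self, b, z, p, r):
        antigen = AntigenParams("a", b, p)
        clone = _clone(z=z)
        kp = k_prime(antigen, clone)
        traj = iterate(antigen, clone, r, 10_000)
        dev = np.abs(traj - kp)
        assert dev[-1] / kp < 1e-6
        # |N_t - K'| eventually decreasing
        tail = dev[-100:]
        assert (np.diff(tail) <= 1e-12).all()


class TestCytokineAmplifiedStep:
    def test_ck_one_reproduces_plain_step_bitwise(self):
        antigen, clone = _antigen(), _clone()
        plain = iterate(antigen, clone, 1.0, 500)
        amplified = iterate(antigen, clone, 1.0, 500,
                            step=cytokine_amplified_step, ck=1.0)
        assert (plain == amplified).all()

    def test_factor_is_identity_at_capacity(self):
        antigen, clone = _antigen(), _clone()
        kp = k_prime(antigen, clone)
        assert cytokine_amplified_step(kp, 3, antigen, clone, 1.0, ck=2.0) \
            == logistic_step(kp, 3, antigen, clone, 1.0)

    def test_half_capacity_factor_arithmetic(self):
        antigen, clone = _antigen(), _clone()
        kp = k_prime(antigen, clone)
        base = logistic_step(kp / 2, 2, antigen, clone, 1.0)
        amp = cytokine_amplified_step(kp / 2, 2, antigen, clone, 1.0,
                                      ck=2.0)
        assert amp == pytest.approx(2.0 ** (2 * 0.5) * base)

    def test_negative_ck_errors(self):
        with pytest.raises(ValueError):
            cytokine_amplified_step(1.0, 1, _antigen(), _clone(), 1.0,
                                    ck=-0.5)


class TestAlloTensor:
    def test_unit_affinities_identity_recognition(self):
        antigens = [_antigen(b=1.0, aid=f"a{i}") for i in range(2)]
        clones = [_clone(z=1.0, cid=f"c{i}") for i in range(2)]
        tensor = build_allo_tensor(antigens, clones)
        assert (tensor.entries == np.eye(2)).all()

    def test_full_recognition_outer_product(self):
        antigens = [_antigen(b=0.02, aid="a0"), _antigen(b=0.01, aid="a1")]
        clones = [_clone(z=0.5, cid="c0"), _clone(z=0.2, cid="c1")]
        tensor = build_allo_tensor(antigens, clones, np.ones((2, 2)))
        assert np.allclose(tensor.entries,
                           [[0.01, 0.004], [0.005, 0.002]])

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            build_allo_tensor([_antigen()], [_clone(), _clone(cid="d")],
                              np.ones((2, 2)))


class TestTransformRepertoire:
    def _setup(self, m=3, seed=0, **spec_kw):
        from allodyn import SynthSpec, synth_repertoire
        clones, antigens, rec = synth_repertoire(
            m, SynthSpec(**spec_kw), seed=seed)
        tensor = build_allo_tensor(antigens, clones, rec)
        return tensor, antigens, clones

    def test_single_clone_reduces_to_iterated_step(self):
        tensor, antigens, clones = self._setup(m=1)
        traj = transform_repertoire(tensor, antigens, clones,
                                    config=SimulationConfig(t_max=200))
        manual = iterate(antigens[0], clones[0], 1.0, 200)
        assert (traj.counts[0] == manual).all()

    def test_aggregate_is_clone_sum_and_order_invariant(self):
        tensor, antigens, clones = self._setup(m=4)
        cfg = SimulationConfig(t_max=100)
        traj = transform_repertoire(tensor, antigens, clones, config=cfg)
        assert traj.aggregate == pytest.approx(traj.counts.sum(axis=0))
        perm = [2, 0, 3, 1]
        tensor_p = build_allo_tensor(
            [antigens[i] for i in perm], [clones[i] for i in perm],
            tensor.recognition[np.ix_(perm, perm)])
        traj_p = transform_repertoire(
            tensor_p, [antigens[i] for i in perm],
            [clones[i] for i in perm], config=cfg)
        assert traj_p.aggregate == pytest.approx(traj.aggregate)

    def test_all_checkpoint_engaged_aggregate_flat(self):
        tensor, antigens, clones = self._setup(m=3, cp_rate=0.0)
        traj = transform_repertoire(tensor, antigens, clones,
                                    config=SimulationConfig(t_max=50))
        assert (traj.aggregate == sum(c.n0 for c in clones)).all()

    def test_unrecognised_clone_stays_flat(self):
        antigens = [_antigen(aid="a0")]
        clones = [_clone(cid="c0"), _clone(cid="c1")]
        rec = np.array([[1.0, 0.0]])
        tensor = build_allo_tensor(antigens, clones, rec)
        traj = transform_repertoire(tensor, antigens, clones,
                                    config=SimulationConfig(t_max=50))
        assert (traj.counts[1] == clones[1].n0).all()
        assert traj.driving_antigen["c1"] is None

    def test_class_ii_steady_states_below_class_i(self):
        """With identical clones, scavenging c < 1 lowers every steady
        state below its class I counterpart."""
        tensor, antigens, clones = self._setup(m=3)
        cfg = SimulationConfig(t_max=4000)
        traj_i = transform_repertoire(tensor, antigens, clones, config=cfg)
        antigens_ii = [AntigenParams(a.antigen_id, a.b_affinity,
                                     a.expression, scavenging=0.5)
                       for a in antigens]
        tensor_ii = build_allo_tensor(antigens_ii, clones,
                                      tensor.recognition)
        traj_ii = transform_repertoire(tensor_ii, antigens_ii, clones,
                                       config=cfg)
        assert (traj_ii.counts[:, -1] < traj_i.counts[:, -1]).all()

    def test_trajectory_frame_has_aggregate_rows(self):
        tensor, antigens, clones = self._setup(m=2)
        traj = transform_repertoire(tensor, antigens, clones,
                                    config=SimulationConfig(t_max=10))
        df = traj.to_frame()
        assert set(df["clone_id"]) == {"T000", "T001", "AGGREGATE"}


class TestGvhdProbability:
    @pytest.mark.parametrize("p,expected", [
        ((1.0, 1.0, 1.0), 1.0),
        ((0.0, 0.9, 0.9), 0.0),
        ((0.5, 0.4, 0.25), 0.05),
    ])
    def test_product(self, p, expected):
        assert gvhd_probability(GvhdProbabilityInputs(*p)) == \
            pytest.approx(expected)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            GvhdProbabilityInputs(1.2, 0.5, 0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
           st.floats(0, 1))
    def test_monotone_in_each_factor(self, a, b, c, d):
        lo, hi = sorted((a, d))
        base = gvhd_probability(GvhdProbabilityInputs(lo, b, c))
        assert gvhd_probability(GvhdProbabilityInputs(hi, b, c)) >= base
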