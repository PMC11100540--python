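"""Mixture likelihood against independent oracles; summaries and contrasts."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import vonmises

from wmgate.mixture_model import (
    MixtureParams,
    MixturePriors,
    ReproObservation,
    _MixtureModel,
    _prepare,
    fit_mixture_hierarchical,
    ltm_intrusion_test,
    mixture_density,
    posterior_summary,
    softmax_probs,
)
from wmgate.sampler import PosteriorDraws


def make_obs(response=20.0, target=0.0, others=(90.0, -120.0), ltm=45.0,
             pair_type="old_mismatch"):
    return ReproObservation(
        response=response, target=target, other_items=list(others),
        ltm_color=ltm, set_size=len(others) + 1, pair_type=pair_type,
    )


def ref_vm_deg(x, mu, kappa):
    """Independent per-degree von Mises density via scipy."""
    if kappa == 0:
        return 1.0 / 360.0
    return vonmises.pdf(np.deg2rad(x - mu), kappa) * np.pi / 180.0


@pytest.mark.parametrize(
    "p,kappa",
    [((0.7, 0.1, 0.1, 0.1), 8.0), ((0.25, 0.25, 0.25, 0.25), 2.0),
     ((0.0, 0.5, 0.0, 0.5), 30.0)],
)
def test_density_equals_term_by_term_recomputation(p, kappa):
    obs = make_obs()
    params = MixtureParams.uniform_cells(np.array(p), kappa)
    p_m, p_s, p_g, p_l = p
    brute = (
        p_m * ref_vm_deg(obs.response, obs.target, kappa)
        + p_s * np.mean([ref_vm_deg(obs.response, o, kappa) for o in obs.other_items])
        + p_g / 360.0
        + p_l * ref_vm_deg(obs.response, obs.ltm_color, kappa)
    )
    assert mixture_density(obs, params) == pytest.approx(brute, abs=1e-10)


def test_density_integrates_to_one():
    params = MixtureParams.uniform_cells([0.5, 0.2, 0.2, 0.1], 6.0)
    val, _ = quad(
        lambda x: mixture_density(make_obs(response=x), params), -180, 180, limit=400
    )
    assert val == pytest.approx(1.0, abs=1e-5)


def test_guessing_only_density_is_uniform():
    params = MixtureParams.uniform_cells([0.0, 0.0, 1.0, 0.0], 10.0)
    for x in (-170.0, 0.0, 33.0):
        assert mixture_density(make_obs(response=x), params) == pytest.approx(1 / 360)
    # log-likelihood of n observations is -n log 360
    n = 57
    ll = sum(np.log(mixture_density(make_obs(response=x), params))
             for x in np.linspace(-180, 179, n))
    assert ll == pytest.approx(-n * np.log(360.0))


def test_memory_only_density_peaks_at_target():
    params = MixtureParams.uniform_cells([1.0, 0.0, 0.0, 0.0], 4.0)
    at_target = mixture_density(make_obs(response=0.0), params)
    for x in (-90.0, 20.0, 140.0):
        assert mixture_density(make_obs(response=x), params) <= at_target


def test_density_missing_cell_errors():
    params = MixtureParams(probs={(2, "new_new"): np.array([0.25] * 4)},
                           kappa={2: 5.0})
    with pytest.raises(KeyError):
        mixture_density(make_obs(), params)


def test_mixture_params_validation():
    with pytest.raises(ValueError):
        MixtureParams(probs={(2, "new_new"): np.array([0.5, 0.5, 0.5, -0.5])},
                      kappa={2: 1.0})
    with pytest.raises(ValueError):
        MixtureParams.uniform_cells([0.25, 0.25, 0.25, 0.25], -2.0)


def test_softmax_link():
    assert softmax_probs((0.0, 0.0, 0.0)) == pytest.approx([0.25] * 4)
    # invariant to a common shift only via the fixed reference; ordering holds
    p = softmax_probs((2.0, 0.0, -1.0))
    assert p[0] > p[1] > p[3] and p.sum() == pytest.approx(1.0)


def test_observation_validates_other_items():
    with pytest.raises(ValueError):
        ReproObservation(0.0, 0.0, [10.0], 0.0, set_size=3, pair_type="new_new")


def test_model_logp_matches_independent_density_sum(small_mixture_cohort):
    """Hierarchical log-likelihood at zero deviations equals the sum of
    per-observation log mixture densities computed independently."""
    data = small_mixture_cohort.data
    md = _prepare(data)
    model = _MixtureModel(md, MixturePriors())
    x = model.init_point()
    L, g, z, log_sd = model.unpack(x)
    L[:, 0], L[:, 1], L[:, 2] = 1.2, -0.3, 0.4
    g[:] = np.log(7.0)

    probs = softmax_probs((1.2, -0.3, 0.4))
    params = MixtureParams.uniform_cells(probs, 7.0)
    brute = 0.0
    for _, grp in data.groupby(["participant", "block", "trial"]):
        cols = grp["target_color_deg"].to_numpy()
        for i, (_, row) in enumerate(grp.iterrows()):
            obs = ReproObservation(
                response=row.response_deg, target=row.target_color_deg,
                other_items=list(np.delete(cols, i)), ltm_color=row.ltm_color_deg,
                set_size=row.set_size, pair_type=row.pair_type,
            )
            brute += np.log(mixture_density(obs, params))
    assert _loglik_at(model, x) == pytest.approx(brute, rel=1e-9)


def _loglik_at(model, x):
    """Log-likelihood alone: total minus analytically recomputed priors."""
    L, g, z, log_sd = model.unpack(x)
    pri = model.priors
    sd = np.exp(log_sd)
    prior = (
        -0.5 * float((L ** 2).sum()) / pri.logit_sd ** 2
        - 0.5 * float(((g - pri.log_kappa_mean) ** 2).sum()) / pri.log_kappa_sd ** 2
        - 0.5 * float((z ** 2).sum())
        + float((-0.5 * sd ** 2 / pri.part_sd_scale ** 2 + log_sd).sum())
    )
    lp, _ = model.logp_grad(x)
    return lp - prior


def test_posterior_summary_and_hdi(rng):
    x = rng.standard_normal(100_000)
    s = posterior_summary(x)
    assert s["mean"] == pytest.approx(0.0, abs=0.02)
    assert s["hdi"][0] == pytest.approx(-1.96, abs=0.05)
    assert s["hdi"][1] == pytest.approx(1.96, abs=0.05)
    with pytest.raises(ValueError):
        posterior_summary(x[:50])


def test_ltm_intrusion_test_is_marginal_difference(rng):
    a = rng.uniform(0, 0.4, size=(2, 500))
    b = rng.uniform(0, 0.4, size=(2, 500))
    draws = PosteriorDraws({"P_LTM[4,old_mismatch]": a, "P_LTM[4,new_new]": b})
    diff = ltm_intrusion_test(draws, 4)
    np.testing.assert_allclose(diff, a.reshape(-1) - b.reshape(-1))
    with pytest.raises(KeyError):
        ltm_intrusion_test(draws, 2)


def test_fit_requires_ltm_colors(small_mixture_cohort):
    data = small_mixture_cohort.data.copy()
    data.loc[data.index[0], "ltm_color_deg"] = np.nan
    with pytest.raises(ValueError, match="ltm_color"):
        fit_mixture_hierarchical(data, n_chains=1, n_warmup=10, n_samples=10, seed=0)
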