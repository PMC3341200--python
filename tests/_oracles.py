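"""Independent oracles for the model right-hand side.

The derivative is re-assembled here as (stoichiometry matrix) x (rate-law
vector) from the reaction scheme, species by species, independently of
the packed implementation in ``pias3net.model``; the ubiquitinated
fraction's dynamics are re-derived from the printed one-minute-update
ratio forms.  These constructions are only ever used as test references.
"""

from __future__ import annotations

import numpy as np

from pias3net.model import STATE_NAMES
from pias3net.params import CoreParameters, complex_degradation_rate

_I = {name: j for j, name in enumerate(STATE_NAMES)}


def _reactions(y: np.ndarray, p: CoreParameters, erkp: float, jakp: float):
    """(stoichiometry, rate) pairs for every reaction in the scheme."""
    g = y.__getitem__
    M, M73, M409, Mpp = (g(_I[s]) for s in ("MITF", "MITFp73", "MITFp409", "MITFpp"))
    P, PM, PM73, PM409, PMpp = (g(_I[s]) for s in (
        "PIAS3", "PIAS3_MITF", "PIAS3_MITFp73", "PIAS3_MITFp409", "PIAS3_MITFpp"))
    RK, RKp = g(_I["RSK1"]), g(_I["RSK1p"])
    S, Sp, PSp, R = g(_I["STAT3"]), g(_I["STAT3p"]), g(_I["PIAS3_STAT3p"]), g(_I["R"])

    rxns: list[tuple[dict[str, float], float]] = []

    # production
    rxns.append(({"MITF": +1}, p.p_MITF))
    rxns.append(({"PIAS3": +1}, p.p_PIAS3))
    rxns.append(({"STAT3": +1}, p.p_STAT3))

    # RSK1 (de)phosphorylation, ERK catalysed
    rxns.append(({"RSK1": -1, "RSK1p": +1}, p.k_Rp_plus * erkp * RK))
    rxns.append(({"RSK1p": -1, "RSK1": +1}, p.k_Rp_minus * RKp))

    # S73 phosphorylation: ERK catalysed + autonomous, shared reverse rate
    for sub, prod, amt_s, amt_p in (
        ("MITF", "MITFp73", M, M73),
        ("MITFp409", "MITFpp", M409, Mpp),
        ("PIAS3_MITF", "PIAS3_MITFp73", PM, PM73),
        ("PIAS3_MITFp409", "PIAS3_MITFpp", PM409, PMpp),
    ):
        rxns.append(({sub: -1, prod: +1}, p.k_Mp73E_plus * erkp * amt_s))
        rxns.append(({sub: -1, prod: +1}, p.k_Mp73a_plus * amt_s))
        rxns.append(({prod: -1, sub: +1}, p.k_Mp73_minus * amt_p))

    # S409 phosphorylation, RSK1p catalysed
    for sub, prod, amt_s, amt_p in (
        ("MITF", "MITFp409", M, M409),
        ("MITFp73", "MITFpp", M73, Mpp),
        ("PIAS3_MITF", "PIAS3_MITFp409", PM, PM409),
        ("PIAS3_MITFp73", "PIAS3_MITFpp", PM73, PMpp),
    ):
        rxns.append(({sub: -1, prod: +1}, p.k_Mp409_plus * RKp * amt_s))
        rxns.append(({prod: -1, sub: +1}, p.k_Mp409_minus * amt_p))

    # PIAS3 binding
    for free, cplx, ass, diss, amt_f, amt_c in (
        ("MITF", "PIAS3_MITF", p.k_Mass, p.k_Mdiss, M, PM),
        ("MITFp73", "PIAS3_MITFp73", p.k_Mp73ass, p.k_Mp73diss, M73, PM73),
        ("MITFp409", "PIAS3_MITFp409", p.k_Mp409ass, p.k_Mp409diss, M409, PM409),
        ("MITFpp", "PIAS3_MITFpp", p.k_Mppass, p.k_Mppdiss, Mpp, PMpp),
        ("STAT3p", "PIAS3_STAT3p", p.k_Spass, p.k_Spdiss, Sp, PSp),
    ):
        rxns.append(({free: -1, "PIAS3": -1, cplx: +1}, ass * amt_f * P))
        rxns.append(({cplx: -1, free: +1, "PIAS3": +1}, diss * amt_c))

    # STAT3 (de)phosphorylation, JAK catalysed
    rxns.append(({"STAT3": -1, "STAT3p": +1}, p.k_Sp_plus * jakp * S))
    rxns.append(({"STAT3p": -1, "STAT3": +1}, p.k_Sp_minus * Sp))

    # degradation; S73-bearing species degrade in proportion to R
    g73R = p.gamma_MITFp73 * R
    rxns.append(({"MITF": -1}, p.gamma_MITF * M))
    rxns.append(({"MITFp73": -1}, g73R * M73))
    rxns.append(({"MITFp409": -1}, p.gamma_MITFp409 * M409))
    rxns.append(({"MITFpp": -1}, g73R * Mpp))
    rxns.append(({"MITFpp": -1}, p.gamma_MITFp409 * Mpp))
    rxns.append(({"PIAS3": -1}, p.gamma_PIAS3 * P))
    rxns.append(({"PIAS3_MITF": -1},
                 complex_degradation_rate(p.gamma_MITF, p.gamma_PIAS3) * PM))
    rxns.append(({"PIAS3_MITFp73": -1},
                 complex_degradation_rate(g73R, p.gamma_PIAS3) * PM73))
    rxns.append(({"PIAS3_MITFp409": -1},
                 complex_degradation_rate(p.gamma_MITFp409, p.gamma_PIAS3) * PM409))
    rxns.append(({"PIAS3_MITFpp": -1},
                 complex_degradation_rate(g73R, p.gamma_PIAS3) * PMpp))
    rxns.append(({"PIAS3_MITFpp": -1},
                 complex_degradation_rate(p.gamma_MITFp409, p.gamma_PIAS3) * PMpp))
    rxns.append(({"STAT3": -1}, p.gamma_STAT3 * S))
    rxns.append(({"STAT3p": -1}, p.gamma_STAT3 * Sp))
    rxns.append(({"PIAS3_STAT3p": -1},
                 complex_degradation_rate(p.gamma_STAT3, p.gamma_PIAS3) * PSp))
    return rxns


def ubiquitination_rate_literal(y: np.ndarray, p: CoreParameters, erkp: float) -> float:
    """dR/dt from the printed one-minute-update ratio forms.

    Valid for R > 0 and a positive dilution denominator (the only regime
    in which the printed ratios are defined).
    """
    R = y[_I["R"]]
    a = 1.0
    g73 = p.gamma_MITFp73
    B = y[_I["MITFp73"]] + y[_I["MITFpp"]]
    term_i = (1.0 - R) * erkp * p.k_u
    # R' = (1 - gamma*a) / (1/R - gamma*a): the tagged fraction after one
    # minute of ubiquitin-mediated degradation of the tagged pool
    r_prime = (1.0 - g73 * a) / (1.0 / R - g73 * a)
    term_ii = -(R - r_prime) / a
    # R'' = R * B / (B + (p_MITF - MITFp409*gamma_MITFp409) * a): the tagged
    # fraction after one minute of fresh (untagged) production influx
    influx = p.p_MITF - y[_I["MITFp409"]] * p.gamma_MITFp409
    r_pp = R * B / (B + influx * a)
    term_iii = -(R - r_pp) / a
    return term_i + term_ii + term_iii


def stoichiometry_rhs(
    y: np.ndarray, p: CoreParameters, erkp: float, jakp: float
) -> np.ndarray:
    """Full derivative vector: S x v for the species, literal forms for R."""
    out = np.zeros(len(STATE_NAMES))
    for stoich, rate in _reactions(y, p, erkp, jakp):
        for name, coeff in stoich.items():
            out[_I[name]] += coeff * rate
    out[_I["R"]] = ubiquitination_rate_literal(y, p, erkp)
    return out


def random_admissible_state(
    rng: np.random.Generator, max_amount: float = 90.0
) -> np.ndarray:
    """Random positive state with R in (0, 1).

    Amounts are capped so that the printed production-dilution denominator
    stays positive at default parameters, keeping the literal ratio forms
    well defined.
    """
    y = rng.uniform(0.1, max_amount, size=len(STATE_NAMES))
    y[_I["R"]] = rng.uniform(0.01, 0.99)
    return y
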