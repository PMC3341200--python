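"""Core parameter set of the MITF-PIAS3-STAT3 network model.

The model has 30 core rate/production/degradation constants plus the fixed
total amount of RSK1.  All amounts are in the model's arbitrary unit (au)
and all times in minutes; second-order rate constants are au^-1 min^-1,
first-order constants min^-1, production rates au min^-1, and the two
kinase inputs (resting phospho-ERK and phospho-JAK levels) are amounts.

Two published versions of the PIAS3 production rate are in circulation:
the parameter table prints 0.262 au/min while the experiment protocols are
all anchored to a baseline of 1.262 au/min.  Both are exposed as parameter
"dialects" (``methods`` -- the default -- and ``table1``).
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

__all__ = [
    "PARAM_NAMES",
    "CoreParameters",
    "make_default_parameters",
    "complex_degradation_rate",
    "load_parameters",
    "save_parameters",
]

#: Canonical ordering of the 30 core parameters (ASCII transliteration of
#: the published symbols).  This ordering is used for parameter vectors in
#: the sensitivity analysis and for the packed array handed to the ODE
#: right-hand side.
PARAM_NAMES: tuple[str, ...] = (
    "k_Mp73E_plus",   # MITF S73 phosphorylation, ERK catalysed (au^-1 min^-1)
    "k_Mp73_minus",   # MITF S73 de-phosphorylation (min^-1)
    "k_Mp73a_plus",   # MITF S73 auto-phosphorylation (min^-1)
    "k_Mp409_plus",   # MITF S409 phosphorylation, RSK1p catalysed (au^-1 min^-1)
    "k_Mp409_minus",  # MITF S409 de-phosphorylation (min^-1)
    "k_Mass",         # MITF/PIAS3 association (au^-1 min^-1)
    "k_Mdiss",        # MITF/PIAS3 dissociation (min^-1)
    "k_Mp73ass",      # MITFp73/PIAS3 association (au^-1 min^-1)
    "k_Mp73diss",     # MITFp73/PIAS3 dissociation (min^-1)
    "k_Mp409ass",     # MITFp409/PIAS3 association (au^-1 min^-1)
    "k_Mp409diss",    # MITFp409/PIAS3 dissociation (min^-1)
    "k_Mppass",       # MITFpp/PIAS3 association (au^-1 min^-1)
    "k_Mppdiss",      # MITFpp/PIAS3 dissociation (min^-1)
    "k_Sp_plus",      # STAT3 phosphorylation, JAKp catalysed (au^-1 min^-1)
    "k_Sp_minus",     # STAT3 de-phosphorylation (min^-1)
    "k_Spass",        # STAT3p/PIAS3 association (au^-1 min^-1)
    "k_Spdiss",       # STAT3p/PIAS3 dissociation (min^-1)
    "p_MITF",         # MITF production (au min^-1)
    "gamma_MITF",     # MITF degradation (min^-1)
    "gamma_MITFp73",  # MITFp73 degradation, applies to ubiquitinated part (min^-1)
    "gamma_MITFp409", # MITFp409 degradation (min^-1)
    "p_PIAS3",        # PIAS3 production (au min^-1)
    "gamma_PIAS3",    # PIAS3 degradation (min^-1)
    "p_STAT3",        # STAT3 production (au min^-1)
    "gamma_STAT3",    # STAT3 degradation (min^-1)
    "k_Rp_plus",      # RSK1 phosphorylation, ERKp catalysed (au^-1 min^-1)
    "k_Rp_minus",     # RSK1 de-phosphorylation (min^-1)
    "ERKp_baseline",  # resting phospho-ERK level (au)
    "JAKp_baseline",  # resting phospho-JAK level (au)
    "k_u",            # MITF ubiquitination (au^-1 min^-1)
)

_DEFAULTS = {
    "k_Mp73E_plus": 0.00015,
    "k_Mp73_minus": 0.03,
    "k_Mp73a_plus": 0.025,
    "k_Mp409_plus": 0.0001,
    "k_Mp409_minus": 0.04,
    "k_Mass": 0.01,
    "k_Mdiss": 1.0,
    "k_Mp73ass": 0.03,
    "k_Mp73diss": 0.5,
    "k_Mp409ass": 0.0001,
    "k_Mp409diss": 1.0,
    "k_Mppass": 0.01,
    "k_Mppdiss": 1.0,
    "k_Sp_plus": 0.0002,
    "k_Sp_minus": 0.04,
    "k_Spass": 0.005,
    "k_Spdiss": 0.2,
    "p_MITF": 1.0,
    "gamma_MITF": 0.0012,
    "gamma_MITFp73": 0.02,
    "gamma_MITFp409": 0.01,
    "p_PIAS3": 1.262,  # 0.262 under the "table1" dialect
    "gamma_PIAS3": 0.008,
    "p_STAT3": 0.211,
    "gamma_STAT3": 0.002,
    "k_Rp_plus": 0.0004,
    "k_Rp_minus": 0.04,
    "ERKp_baseline": 10.0,
    "JAKp_baseline": 10.0,
    "k_u": 0.0001,
}

#: Fixed total RSK1 amount (au); the kinase is conserved, only its
#: phosphorylation state is dynamic.  Not part of the 30 sampled parameters.
RSK1_TOTAL_DEFAULT = 500.0

DIALECTS = ("methods", "table1")


@dataclass(frozen=True)
class CoreParameters:
    """The 30 core constants plus the conserved RSK1 total.

    Instances are immutable; use :meth:`replace` to derive perturbed sets.
    """

    k_Mp73E_plus: float
    k_Mp73_minus: float
    k_Mp73a_plus: float
    k_Mp409_plus: float
    k_Mp409_minus: float
    k_Mass: float
    k_Mdiss: float
    k_Mp73ass: float
    k_Mp73diss: float
    k_Mp409ass: float
    k_Mp409diss: float
    k_Mppass: float
    k_Mppdiss: float
    k_Sp_plus: float
    k_Sp_minus: float
    k_Spass: float
    k_Spdiss: float
    p_MITF: float
    gamma_MITF: float
    gamma_MITFp73: float
    gamma_MITFp409: float
    p_PIAS3: float
    gamma_PIAS3: float
    p_STAT3: float
    gamma_STAT3: float
    k_Rp_plus: float
    k_Rp_minus: float
    ERKp_baseline: float
    JAKp_baseline: float
    k_u: float
    RSK1_total: float = RSK1_TOTAL_DEFAULT

    def __post_init__(self) -> None:
        for name in PARAM_NAMES + ("RSK1_total",):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {value}")
        # A positive association rate with a zero dissociation rate would
        # make the corresponding complex an absorbing state.
        for ass, diss in (
            ("k_Mass", "k_Mdiss"),
            ("k_Mp73ass", "k_Mp73diss"),
            ("k_Mp409ass", "k_Mp409diss"),
            ("k_Mppass", "k_Mppdiss"),
            ("k_Spass", "k_Spdiss"),
        ):
            if getattr(self, ass) > 0 and getattr(self, diss) <= 0:
                raise ValueError(f"{diss} must be > 0 when {ass} > 0")

    def replace(self, **overrides: float) -> "CoreParameters":
        """Return a copy with the given fields replaced.

        Unknown field names raise ``ValueError`` with a nearest-name hint.
        """
        valid = set(PARAM_NAMES) | {"RSK1_total"}
        for key in overrides:
            if key not in valid:
                hint = difflib.get_close_matches(key, sorted(valid), n=1)
                extra = f"; did you mean {hint[0]!r}?" if hint else ""
                raise ValueError(f"unknown parameter {key!r}{extra}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES + ("RSK1_total",)}

    def as_array(self):
        """Pack the 30 core parameters + RSK1_total into a float64 vector."""
        import numpy as np

        return np.array(
            [getattr(self, name) for name in PARAM_NAMES] + [self.RSK1_total],
            dtype=np.float64,
        )

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.to_dict().items())


def make_default_parameters(dialect: str = "methods") -> CoreParameters:
    """Published default parameter set.

    Parameters
    ----------
    dialect
        ``"methods"`` (default) uses the PIAS3 production rate of
        1.262 au/min that all experiment protocols are anchored to;
        ``"table1"`` uses the 0.262 au/min printed in the parameter table.
        All other values are identical between the dialects.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    values = dict(_DEFAULTS)
    if dialect == "table1":
        values["p_PIAS3"] = 0.262
    return CoreParameters(**values)


def complex_degradation_rate(gamma_a: float, gamma_b: float) -> float:
    """Degradation rate of a 1:1 protein complex.

    Proteins in complex are more stable than free ones: the complex
    degrades at 20% of the mean of its constituents' free degradation
    rates, i.e. ``(gamma_a + gamma_b) / 10``.
    """
    if gamma_a < 0 or gamma_b < 0:
        raise ValueError("degradation rates must be >= 0")
    return (gamma_a + gamma_b) / 10.0


def save_parameters(params: CoreParameters, path: str | Path) -> None:
    """Write a parameter set as a flat key-value file (JSON or YAML by suffix)."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


def load_parameters(path: str | Path) -> CoreParameters:
    """Read a flat key-value parameter file written by :func:`save_parameters`.

    Missing keys fall back to the methods-dialect defaults; unknown keys
    raise with a nearest-name suggestion.
    """
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        data = yaml.safe_load(path.read_text()) or {}
    else:
        data = json.loads(path.read_text())
    return make_default_parameters("methods").replace(**{k: float(v) for k, v in data.items()})
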