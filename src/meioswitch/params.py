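"""Parameter sets for the meiosis subsystem and the integrated model.

A :class:`ParameterSet` is an immutable mapping of parameter name to
nonnegative value with a closed name set: loading or constructing a set
with unknown or missing names fails loudly, listing the offending names.
Time unit is minutes throughout; concentrations are dimensionless.

The bundled defaults are the package's calibrated reference parameter
set: rate constants for Ste11/Mei2 turnover derive from the reported
half-lives of the proteins (both are unstable, half-lives of minutes to
tens of minutes), and the remaining values were chosen so that the model
reproduces the qualitative behaviour of the wild type and the mutant
panel under nitrogen-rich and starvation inputs.
"""

from __future__ import annotations

import json
import re
from collections.abc import Mapping
from pathlib import Path

__all__ = [
    "ParameterSet",
    "MEIOSIS_DEFAULTS",
    "CELLCYCLE_DEFAULTS",
    "INTEGRATED_DEFAULTS",
    "default_parameters",
    "load_parameters",
    "write_parameters",
]


# --- Ste11-Mei2-Pat1 subsystem -------------------------------------------
# Hill thresholds on nuclear Ste11 are ordered k_mmei2 < k_mste11 < k_mphe
# < k_mmat: Mei2 and the autoregulatory loop respond first, pheromone
# signalling (PheS) needs more Ste11n, and Mat1-Pm has the highest
# activation threshold so that it only appears after the PheS boost.
MEIOSIS_DEFAULTS: dict[str, float] = {
    # Ste11 synthesis: basal + (Rst2-linked + autoregulatory) * Rpol
    "ks11b": 0.002,     # constitutive synthesis (nmt1-ste11 override target)
    "ks11r": 2.0,       # Rst2-linked synthesis coefficient
    "ks11a": 0.4,       # Ste11n autoregulatory synthesis coefficient
    "k_mste11": 0.12,   # half-saturation of Ste11 autoregulation
    "hs": 4.0,          # Hill coefficient of Ste11 autoregulation
    "kd_ste11": 0.10,   # Ste11 degradation (unstable, t1/2 ~ 7 min)
    "w_ste11": 1.0,     # Ste11 DNA-binding competence (T82 phospho target)
    # Ste11 localization
    "k_imste11": 0.25,  # basal nuclear import rate
    "k_imphe": 6.0,     # PheS boost of nuclear import
    "k_exste11": 0.10,  # basal nuclear export rate
    "k_expat": 8.0,     # Pat1-dependent export (14-3-3 retention)
    "k_exnut": 2.0,     # cooperative Tor2*PKA-dependent export
    "k_tapat": 2.0,     # Pat1 inhibition of Ste11n transcriptional activity
    # Rst2 (algebraic): repressed by PKA
    "k_mpka": 0.66,
    "h_pka": 4.0,
    # Rpol (algebraic): Pol II CTD phosphorylation promoted by total Mei2
    "rpol_b": 0.05,     # basal Rpol activity without Mei2
    "w_rpol": 1.0,      # weight of the Mei2->CTDK-I coupling (lsk1 target)
    "k_mrpol": 0.06,
    "h_rpol": 2.0,
    # Pheromone signalling (lumped Byr2-Byr1-Spk1 = PheS)
    "k_sphe": 0.20,     # Ste11n-driven PheS upregulation rate
    "k_sphe_b": 0.0,    # constitutive PheS synthesis (byr2-DN override)
    "k_mphe": 0.80,
    "h_phe": 4.0,
    "kd_phe": 0.10,
    # Mat1-Pm: requires high Ste11n
    "k_smat": 0.05,
    "k_mmat": 2.50,     # higher threshold than k_mphe
    "h_mat": 4.0,
    "kd_mat": 0.02,
    # Mei3: synthesized from Mat1-Pm (with partner), inhibits Pat1
    "k_smei3": 0.018,
    "k_mmei3": 2.00,
    "h_mei3": 6.0,
    "kd_mei3": 0.05,
    "k_as": 1.0,       # Pat1:Mei3 association (tight stoichiometric)
    "k_di": 1e-4,       # complex dissociation
    "kd_cplx": 1e-4,    # complex turnover (degrades Mei3, recycles Pat1)
    # Pat1
    "pat1_t": 1.0,      # total Pat1
    "k_iphe": 2.0,      # PheS inhibition of Pat1 (rapid equilibrium)
    # Mei2
    "ks_mei2": 0.10,
    "eps_mei2": 0.01,   # basal fraction of Ste11-driven Mei2 synthesis
    "k_mmei2": 0.06,
    "h_mei2": 3.0,
    # second, high-threshold component of Mei2 synthesis: very abundant
    # nuclear Ste11 keeps driving mei2 transcription past the
    # low-threshold saturation (Ste11 overexpression epistasis)
    "ks_mei2h": 0.05,
    "k_mmei2h": 8.0,
    "h_mei2h": 2.0,
    "kd_mei2": 0.05,    # degradation of active (dephosphorylated) Mei2
    "kd_mei2p": 0.20,   # degradation of Pat1-phosphorylated Mei2
    "kp_pat": 40.0,      # Pat1-dependent Mei2 phosphorylation kcat
    "km_p": 0.05,       # Michaelis constant, phosphorylation (zero-order)
    "kdp_mei2": 3.0,   # Mei2 dephosphorylation rate
    "km_dp": 0.05,      # Michaelis constant, dephosphorylation
    # Tor2-site phosphorylation acts as a destabilizer (phospho-degron):
    # active Mei2 degradation is scaled by (1 + kp_tor x tor2); the
    # Pat1-phosphorylated form carries the synergistic double degron,
    # scaled by (1 + kp_torp x tor2 x Pat1 activity)
    "kp_tor": 0.5,      # on active Mei2
    "kp_torp": 10.0,    # on Pat1-phosphorylated Mei2 (needs both kinases)
}


# --- cell-cycle submodel (Novak-school M-phase control + B55 layer) ------
CELLCYCLE_DEFAULTS: dict[str, float] = {
    "ks_cdc13": 0.03,        # cyclin synthesis per unit mass
    "kd_cdc13_b": 0.03,
    "kd_cdc13_ste9": 1.0,
    "kd_cdc13_slp1": 0.10,
    "ka_ste9": 1.0,
    "ka_ste9_slp1": 10.0,
    "j_ste9a": 0.01,
    "ki_ste9_sk": 2.0,
    "ki_ste9_mpf": 35.0,
    "j_ste9i": 0.01,
    "ks_slp1_b": 0.005,
    "ks_slp1_mpf": 0.30,
    "j_slp1": 0.65,
    "w_slp1_b55": 0.55,      # B55 restraint of APC/Slp1 activation
    "h_slp1": 8.0,
    "kd_slp1": 0.10,
    "ka_slp1": 1.0,
    "j_a_slp1": 0.001,
    "ki_slp1": 0.25,
    "j_i_slp1": 0.001,
    "ka_iep": 0.10,
    "ki_iep": 0.04,
    "ks_rum1": 0.10,
    "kd_rum1_b": 0.01,
    "kd_rum1_sk": 1.0,
    "kd_rum1_mpf": 3.0,
    "kdiss": 0.001,          # Cdk1:Cdc13 / Rum1 trimer dissociation
    "ks_sk": 0.10,
    "kd_sk": 0.10,
    "ka_tf_m": 1.5,
    "ki_tf_b": 1.0,
    "ki_tf_mpf": 2.0,
    "j_a_tf": 0.01,
    "j_i_tf": 0.01,
    "v_awee": 0.25,
    "v_iwee": 1.0,
    "j_awee": 0.01,
    "j_iwee": 0.01,
    "v_a25": 1.0,
    "v_i25": 0.25,
    "j_a25": 0.01,
    "j_i25": 0.01,
    "kwee_lo": 0.15,
    "kwee_hi": 1.30,
    "k25_lo": 0.05,
    "k25_hi": 5.0,
    "mu": 0.00433,           # specific growth rate (rich); 0 when starved
    # PP2A:B55 - Ppk18/Igo1 layer (starvation advances mitosis)
    "b55_t": 1.0,
    "k_igo": 0.10,           # Igo1 phosphorylation by Ppk18 (Tor2 off)
    "kdp_igo": 0.20,         # Igo1 dephosphorylation by PP2A:B55
    "k_ib55": 0.10,          # Igo1P inhibition constant on B55
    "eps_b55": 0.10,         # residual Wee1/Cdc25-phosphatase activity
    # intracellular nitrogen pool (sustains cyclin synthesis when starved)
    "n_pool0": 1.80,         # pool released at starvation onset
    "kd_pool": 0.004,        # first-order pool depletion
    # couplings to the meiosis subsystem
    "k_cdk_ste11": 0.30,     # MPF threshold gating Ste11 autoregulation
    "h_cdk_ste11": 4.0,
    "k_rum1_phes": 4.0,      # PheS reduction of Rum1 degradation
    "k_sk_phes": 0.0,        # PheS suppression of starter-kinase synthesis
    # Ste11n-mediated starter-kinase suppression (pheromone-induced G1
    # arrest needs Ste11): steep threshold, so only the sustained nuclear
    # Ste11 of a PheS-engaged G1 cell arrests the cycle
    "a_sk_arrest": 0.0,
    "k_sk_arrest": 5.0,
    "h_sk_arrest": 4.0,
    # division event thresholds on Cdk1:Cdc13 activity
    "mpf_mitotic": 0.40,
    "mpf_exit": 0.10,
}

INTEGRATED_DEFAULTS: dict[str, float] = {**MEIOSIS_DEFAULTS, **CELLCYCLE_DEFAULTS}

_MODEL_DEFAULTS = {
    "meiosis": MEIOSIS_DEFAULTS,
    "cellcycle": CELLCYCLE_DEFAULTS,
    "integrated": INTEGRATED_DEFAULTS,
}

# parameters allowed to be zero-or-positive but with extra constraints
_HILL_COEFFS = {"hs", "h_pka", "h_rpol", "h_phe", "h_mat", "h_mei3",
                "h_mei2", "h_mei2h", "h_slp1", "h_cdk_ste11", "h_sk_arrest"}


class ParameterSet(Mapping):
    """Closed, validated mapping of parameter name -> nonnegative value.

    Instances are immutable; use :meth:`replace` to derive a modified set
    (this is what genotype overrides do).
    """

    def __init__(self, values: Mapping[str, float], model: str = "meiosis"):
        if model not in _MODEL_DEFAULTS:
            raise ValueError(f"unknown model {model!r}")
        ref = _MODEL_DEFAULTS[model]
        vals = {str(k).lower(): float(v) for k, v in values.items()}
        unknown = sorted(set(vals) - set(ref))
        missing = sorted(set(ref) - set(vals))
        if unknown or missing:
            raise ValueError(
                f"parameter name mismatch for model {model!r}: "
                f"unknown={unknown}, missing={missing}"
            )
        for name, v in vals.items():
            if not v >= 0.0:
                raise ValueError(f"parameter {name} must be >= 0, got {v}")
        for name in _HILL_COEFFS & set(vals):
            if vals[name] < 1.0:
                raise ValueError(f"Hill coefficient {name} must be >= 1")
        self._values = vals
        self.model = model

    # Mapping interface
    def __getitem__(self, key):
        return self._values[key.lower()]

    def __iter__(self):
        return iter(self._values)

    def __len__(self):
        return len(self._values)

    def __repr__(self):
        return f"ParameterSet(model={self.model!r}, n={len(self)})"

    def __eq__(self, other):
        return (isinstance(other, ParameterSet)
                and self.model == other.model
                and self._values == other._values)

    def replace(self, **overrides) -> "ParameterSet":
        """Return a new set with the given parameters replaced."""
        vals = dict(self._values)
        for k, v in overrides.items():
            kl = k.lower()
            if kl not in vals:
                raise KeyError(f"unknown parameter {k!r}")
            vals[kl] = float(v)
        return ParameterSet(vals, model=self.model)

    def scale(self, name: str, factor: float) -> "ParameterSet":
        return self.replace(**{name: self[name] * factor})

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)


def default_parameters(model: str = "meiosis") -> ParameterSet:
    """The bundled calibrated defaults for a model."""
    return ParameterSet(_MODEL_DEFAULTS[model], model=model)


_ODE_PAR_RE = re.compile(
    r"^\s*(?:par|p)\s+(.+)$", re.IGNORECASE)


def _parse_ode_lines(text: str) -> dict[str, float]:
    """Extract ``par name=value`` declarations from an XPPAUT .ode file.

    Equations, options, initial conditions and comments are ignored.
    Several comma-separated assignments may share one ``par`` line.
    """
    out: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#")[0].strip()
        if not stripped:
            continue
        m = _ODE_PAR_RE.match(stripped)
        if not m:
            continue
        body = m.group(1)
        for item in body.split(","):
            item = item.strip()
            if not item:
                continue
            if "=" not in item:
                raise ValueError(
                    f"unparsable parameter assignment on line {lineno}: {item!r}")
            name, _, val = item.partition("=")
            try:
                out[name.strip().lower()] = float(val.strip())
            except ValueError as exc:
                raise ValueError(
                    f"bad numeric value on line {lineno}: {item!r}") from exc
    return out


def load_parameters(source, model: str = "meiosis") -> ParameterSet:
    """Load a ParameterSet from an XPPAUT ``.ode`` file or a flat config.

    Flat configs may be YAML, JSON or TOML, all mapping parameter name to
    value.  Names are case-insensitive.  The loader verifies the name set
    against the chosen model and reports the full diff on mismatch.
    """
    path = Path(source)
    text = path.read_text()
    suffix = path.suffix.lower()
    if suffix == ".ode":
        values = _parse_ode_lines(text)
    elif suffix == ".json":
        values = json.loads(text)
    elif suffix == ".toml":
        import tomllib
        values = tomllib.loads(text)
    elif suffix in (".yaml", ".yml"):
        import yaml
        values = yaml.safe_load(text)
    else:
        raise ValueError(f"unsupported parameter file type: {path.name}")
    if not isinstance(values, Mapping) or not values:
        ref = sorted(_MODEL_DEFAULTS[model])
        raise ValueError(
            f"no parameters found in {path.name}; required names: {ref}")
    return ParameterSet(values, model=model)


def write_parameters(params: ParameterSet, dest) -> Path:
    """Write a ParameterSet to ``dest`` (.ode or .json), round-trippable."""
    path = Path(dest)
    if path.suffix.lower() == ".ode":
        lines = [f"par {name}={params[name]!r}" for name in sorted(params)]
        lines.append("done")
        path.write_text("\n".join(lines) + "\n")
    elif path.suffix.lower() == ".json":
        path.write_text(json.dumps(
            {k: params[k] for k in sorted(params)}, indent=1) + "\n")
    else:
        raise ValueError(f"unsupported output type: {path.name}")
    return path


def parameter_manifest(model: str = "integrated") -> str:
    """Plain-text table of parameter names and default values."""
    ref = _MODEL_DEFAULTS[model]
    width = max(len(k) for k in ref)
    lines = [f"{'name':<{width}}  default", f"{'-' * width}  -------"]
    lines += [f"{k:<{width}}  {v:g}" for k, v in sorted(ref.items())]
    return "\n".join(lines)
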