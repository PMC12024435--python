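"""Kinetic-metabolic network model: species, parameters, Michaelis-Menten
flux laws, stoichiometry, and the assembled reaction-rate vector.

The shipped model definition (``data/model_hek293_aav.yaml``) describes the
central-carbon and amino-acid metabolism of HEK293 cells producing
recombinant AAV: glycolysis, TCA cycle, pentose phosphate pathway,
anaplerosis, amino-acid metabolism, nucleotide synthesis, biomass synthesis
and the Rep/capsid protein synthesis reactions.  Units throughout:
concentrations in mM, time in hours, fluxes in mM/h.

Every flux follows a product-of-saturation-terms Michaelis-Menten law

    v = vmax * prod_s [S_s] / (Km_s + [S_s])

optionally minus an analogous reverse product for reversible reactions.
Species dynamics are the dense mass balance dC/dt = S @ v(C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ModelValidationError",
    "Species",
    "Parameter",
    "FluxLaw",
    "Reaction",
    "ParameterSet",
    "MetabolicModel",
    "load_model",
    "evaluate_flux",
    "assemble_rates",
    "count_parameters",
]


class ModelValidationError(ValueError):
    """Raised when a model definition violates the schema or cross-references."""


@dataclass(frozen=True)
class Species:
    """A mass-balanced state variable of the network."""

    id: str
    long_name: str = ""
    initial_concentration: float = 0.0  # fitted C_0, mM
    observed: bool = False
    fixed_initial: bool = False

    def __post_init__(self):
        if self.initial_concentration < 0:
            raise ModelValidationError(
                f"species {self.id!r}: negative initial concentration "
                f"{self.initial_concentration}"
            )


@dataclass(frozen=True)
class Parameter:
    """A named nonnegative model quantity (Km, vmax, or initial concentration)."""

    name: str
    kind: str  # "Km" | "vmax" | "initial_concentration"
    value: float
    fitted: bool = True

    _KINDS = ("Km", "vmax", "initial_concentration")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ModelValidationError(
                f"parameter {self.name!r}: unknown kind {self.kind!r}"
            )
        if not math.isfinite(self.value) or self.value < 0:
            raise ModelValidationError(
                f"parameter {self.name!r}: value must be finite and >= 0, "
                f"got {self.value}"
            )


@dataclass(frozen=True)
class FluxLaw:
    """Michaelis-Menten rate law: a forward saturation product and, for
    reversible reactions, a subtracted reverse product."""

    id: str
    forward_vmax: str
    forward_terms: tuple[tuple[str, str], ...]  # (species id, Km parameter name)
    reverse_vmax: str | None = None
    reverse_terms: tuple[tuple[str, str], ...] = ()

    @property
    def reversible(self) -> bool:
        return self.reverse_vmax is not None


@dataclass(frozen=True)
class Reaction:
    """Signed stoichiometry attached to one flux law (reactants < 0)."""

    flux: str
    stoichiometry: Mapping[str, float]

    def __post_init__(self):
        for sid, coef in self.stoichiometry.items():
            if not math.isfinite(coef) or coef == 0:
                raise ModelValidationError(
                    f"reaction {self.flux!r}: coefficient for {sid!r} must be "
                    f"finite and nonzero, got {coef}"
                )


class ParameterSet:
    """Named parameter values: Km_*, vmax_*, and c0_<species>.

    Behaves like a read-mostly mapping; ``updated`` returns a modified copy
    so fitted / perturbed variants never mutate the shipped defaults.
    """

    def __init__(self, values: Mapping[str, float], kinds: Mapping[str, str]):
        unknown = set(values) - set(kinds)
        if unknown:
            raise KeyError(f"values without a registered kind: {sorted(unknown)}")
        self._values = dict(values)
        self._kinds = dict(kinds)

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def __len__(self) -> int:
        return len(self._values)

    def __iter__(self):
        return iter(self._values)

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    def kind(self, name: str) -> str:
        return self._kinds[name]

    def names(self, kind: str | None = None) -> list[str]:
        if kind is None:
            return list(self._values)
        return [n for n in self._values if self._kinds[n] == kind]

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    def updated(self, changes: Mapping[str, float]) -> "ParameterSet":
        unknown = set(changes) - set(self._values)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        merged = dict(self._values)
        merged.update(changes)
        return ParameterSet(merged, self._kinds)

    def copy(self) -> "ParameterSet":
        return ParameterSet(self._values, self._kinds)


class MetabolicModel:
    """Validated network: species registry, parameter registry, flux laws,
    reactions, and the compiled stoichiometric matrix.

    The state vector has ``n_species`` mass-balance entries followed by the
    auxiliary cumulative outputs (Biomass, Rep, Cap in the shipped model),
    which start at 0 and are excluded from parameter counts.
    """

    def __init__(
        self,
        species: Sequence[Species],
        parameters: Sequence[Parameter],
        flux_laws: Sequence[FluxLaw],
        reactions: Sequence[Reaction],
        observation_order: Sequence[str] = (),
        auxiliary_outputs: Sequence[str] = (),
        name: str = "model",
    ):
        self.name = name
        self.species = list(species)
        self.flux_laws = list(flux_laws)
        self.reactions = list(reactions)
        self.observation_order = list(observation_order)
        self.auxiliary_outputs = list(auxiliary_outputs)

        self.species_index = {s.id: i for i, s in enumerate(self.species)}
        if len(self.species_index) != len(self.species):
            raise ModelValidationError("duplicate species ids")
        self._kinetic_params: dict[str, Parameter] = {}
        for p in parameters:
            if p.name in self._kinetic_params:
                raise ModelValidationError(f"duplicate parameter name {p.name!r}")
            self._kinetic_params[p.name] = p

        self._validate()
        self._compile()

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        law_ids = [l.id for l in self.flux_laws]
        if len(set(law_ids)) != len(law_ids):
            raise ModelValidationError("duplicate flux-law ids")
        aux = set(self.auxiliary_outputs)
        if aux & set(self.species_index):
            raise ModelValidationError(
                "auxiliary outputs must not duplicate species ids"
            )

        for law in self.flux_laws:
            refs = [(law.forward_vmax, "vmax")]
            terms = list(law.forward_terms) + list(law.reverse_terms)
            if law.reverse_vmax is not None:
                refs.append((law.reverse_vmax, "vmax"))
            for sid, km in terms:
                if sid not in self.species_index:
                    raise ModelValidationError(
                        f"flux law {law.id!r}: unknown species {sid!r}"
                    )
                refs.append((km, "Km"))
            for pname, kind in refs:
                p = self._kinetic_params.get(pname)
                if p is None:
                    raise ModelValidationError(
                        f"flux law {law.id!r}: unknown parameter {pname!r}"
                    )
                if p.kind != kind:
                    raise ModelValidationError(
                        f"flux law {law.id!r}: parameter {pname!r} has kind "
                        f"{p.kind!r}, expected {kind!r}"
                    )

        counts = {lid: 0 for lid in law_ids}
        for rxn in self.reactions:
            if rxn.flux not in counts:
                raise ModelValidationError(
                    f"reaction references unknown flux law {rxn.flux!r}"
                )
            counts[rxn.flux] += 1
            for sid in rxn.stoichiometry:
                if sid not in self.species_index and sid not in aux:
                    raise ModelValidationError(
                        f"reaction {rxn.flux!r}: unknown species {sid!r}"
                    )
        bad = [lid for lid, c in counts.items() if c != 1]
        if bad:
            raise ModelValidationError(
                f"flux laws must be referenced by exactly one reaction: {bad}"
            )

        missing = [s for s in self.observation_order if s not in self.species_index]
        if missing:
            raise ModelValidationError(f"observation_order unknown species: {missing}")

    def _compile(self) -> None:
        """Precompute index arrays so the ODE right-hand side is loop-free."""
        self.km_names = [p.name for p in self._kinetic_params.values() if p.kind == "Km"]
        self.vmax_names = [
            p.name for p in self._kinetic_params.values() if p.kind == "vmax"
        ]
        km_index = {n: i for i, n in enumerate(self.km_names)}
        vmax_index = {n: i for i, n in enumerate(self.vmax_names)}

        n_states = self.n_states
        flux_index = {l.id: j for j, l in enumerate(self.flux_laws)}
        S = np.zeros((n_states, len(self.flux_laws)))
        state_index = dict(self.species_index)
        for k, aux_id in enumerate(self.auxiliary_outputs):
            state_index[aux_id] = self.n_species + k
        for rxn in self.reactions:
            j = flux_index[rxn.flux]
            for sid, coef in rxn.stoichiometry.items():
                S[state_index[sid], j] += coef
        self.stoichiometric_matrix = S
        self.state_ids = [s.id for s in self.species] + list(self.auxiliary_outputs)

        # one "segment" per saturation product (forward for every law,
        # reverse for the reversible ones)
        t_species, t_km, seg_start = [], [], []
        seg_flux, seg_sign, seg_vmax = [], [], []
        for j, law in enumerate(self.flux_laws):
            for sign, vmax, terms in (
                (1.0, law.forward_vmax, law.forward_terms),
                (-1.0, law.reverse_vmax, law.reverse_terms),
            ):
                if vmax is None:
                    continue
                seg_start.append(len(t_species))
                seg_flux.append(j)
                seg_sign.append(sign)
                seg_vmax.append(vmax_index[vmax])
                for sid, km in terms:
                    t_species.append(self.species_index[sid])
                    t_km.append(km_index[km])
        self._term_species = np.asarray(t_species, dtype=np.intp)
        self._term_km = np.asarray(t_km, dtype=np.intp)
        self._seg_start = np.asarray(seg_start, dtype=np.intp)
        self._seg_flux = np.asarray(seg_flux, dtype=np.intp)
        self._seg_sign = np.asarray(seg_sign)
        self._seg_vmax = np.asarray(seg_vmax, dtype=np.intp)
        seg_len = np.diff(np.append(self._seg_start, len(t_species)))
        self._term_seg = np.repeat(np.arange(len(seg_start), dtype=np.intp), seg_len)

    # -- basic facts ---------------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_states(self) -> int:
        return self.n_species + len(self.auxiliary_outputs)

    @property
    def n_fluxes(self) -> int:
        return len(self.flux_laws)

    def flux_law(self, law_id: str) -> FluxLaw:
        for law in self.flux_laws:
            if law.id == law_id:
                return law
        raise KeyError(law_id)

    def observed_indices(self) -> np.ndarray:
        return np.asarray(
            [self.species_index[s] for s in self.observation_order], dtype=np.intp
        )

    # -- parameters ----------------------------------------------------------------

    def parameter_set(self) -> ParameterSet:
        """Shipped defaults: all kinetic parameters plus c0_<species>."""
        values: dict[str, float] = {}
        kinds: dict[str, str] = {}
        for p in self._kinetic_params.values():
            values[p.name] = p.value
            kinds[p.name] = p.kind
        for s in self.species:
            values[f"c0_{s.id}"] = s.initial_concentration
            kinds[f"c0_{s.id}"] = "initial_concentration"
        return ParameterSet(values, kinds)

    def free_initial_parameters(self) -> list[str]:
        """c0 names legitimately subject to fitting (non-measured species)."""
        return [f"c0_{s.id}" for s in self.species if not s.fixed_initial]

    def initial_state(self, params: ParameterSet) -> np.ndarray:
        c0 = np.array([params[f"c0_{s.id}"] for s in self.species])
        return np.concatenate([c0, np.zeros(len(self.auxiliary_outputs))])

    def _param_arrays(self, params: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
        km = np.array([params[n] for n in self.km_names])
        vmax = np.array([params[n] for n in self.vmax_names])
        return km, vmax

    # -- kinetics ------------------------------------------------------------------

    def flux_vector(self, state: np.ndarray, km: np.ndarray, vmax: np.ndarray
                    ) -> np.ndarray:
        """All fluxes at a state, given Km/vmax value arrays in model order.

        Concentrations are floored at 0 so integrator overshoot below zero
        cannot drive a saturation term negative.
        """
        conc = np.maximum(state[: self.n_species], 0.0)
        c = conc[self._term_species]
        sat = c / (km[self._term_km] + c)
        prod = np.multiply.reduceat(sat, self._seg_start) if len(sat) else np.ones(0)
        v = np.zeros(self.n_fluxes)
        np.add.at(v, self._seg_flux, self._seg_sign * vmax[self._seg_vmax] * prod)
        return v

    def rates(self, state: np.ndarray, km: np.ndarray, vmax: np.ndarray) -> np.ndarray:
        """dC/dt = S @ v for the full (species + auxiliary) state vector."""
        return self.stoichiometric_matrix @ self.flux_vector(state, km, vmax)

    def rates_jacobian(
        self, state: np.ndarray, km: np.ndarray, vmax: np.ndarray
    ) -> np.ndarray:
        """Analytic d(dC/dt)/dC, consistent with the concentration floor.

        For a saturation term s(c) = c/(Km+c) the derivative is
        Km/(Km+c)^2 (0 where the state is clipped); each flux derivative is
        the product of the other saturation terms times that, and the state
        Jacobian is S @ dv/dC.  Supplying this to the stiff solver avoids
        ~50 finite-difference RHS evaluations per solver-Jacobian update.
        """
        conc = np.maximum(state[: self.n_species], 0.0)
        c = conc[self._term_species]
        kmv = km[self._term_km]
        denom = kmv + c
        sat = c / denom
        dsat = np.where(state[: self.n_species][self._term_species] < 0, 0.0,
                        kmv / denom**2)
        # product over the other terms of each segment, robust to zeros
        zero = sat == 0.0
        nz_sat = np.where(zero, 1.0, sat)
        if len(sat):
            prod_nz = np.multiply.reduceat(nz_sat, self._seg_start)
            n_zero = np.add.reduceat(zero.astype(np.intp), self._seg_start)
        else:
            prod_nz = np.ones(0)
            n_zero = np.zeros(0, dtype=np.intp)
        seg = self._term_seg
        prod_others = np.where(
            n_zero[seg] == 0,
            prod_nz[seg] / nz_sat,
            np.where((n_zero[seg] == 1) & zero, prod_nz[seg], 0.0),
        )
        coef = (self._seg_sign[seg] * vmax[self._seg_vmax[seg]]
                * prod_others * dsat)
        dv = np.zeros((self.n_fluxes, self.n_species))
        np.add.at(dv, (self._seg_flux[seg], self._term_species), coef)
        jac = np.zeros((self.n_states, self.n_states))
        jac[:, : self.n_species] = self.stoichiometric_matrix @ dv
        return jac


# -- module-level operations -------------------------------------------------------


def _parse_law(entry: Mapping) -> FluxLaw:
    def side(block):
        if block is None:
            return None, ()
        terms = tuple((str(s), str(k)) for s, k in block["terms"])
        return str(block["vmax"]), terms

    f_vmax, f_terms = side(entry["forward"])
    r_vmax, r_terms = side(entry.get("reverse"))
    return FluxLaw(str(entry["id"]), f_vmax, f_terms, r_vmax, r_terms)


def load_model(source=None) -> MetabolicModel:
    """Load and validate a model definition.

    Parameters
    ----------
    source
        A path to a YAML definition, an already-parsed mapping, or None for
        the shipped HEK293/rAAV model.

    Raises
    ------
    ModelValidationError
        On dangling references, duplicate ids, negative values, or schema
        violations; the message names the offending entity.
    """
    if source is None:
        ref = resources.files("raavmet.data") / "model_hek293_aav.yaml"
        raw = yaml.safe_load(ref.read_text())
    elif isinstance(source, Mapping):
        raw = source
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)

    try:
        species = [
            Species(
                id=str(e["id"]),
                long_name=str(e.get("name", "")),
                initial_concentration=float(e["c0"]),
                observed=bool(e.get("observed", False)),
                fixed_initial=bool(e.get("fixed_initial", False)),
            )
            for e in raw["species"]
        ]
        params = [
            Parameter(name, "Km", float(v))
            for name, v in raw.get("parameters", {}).get("km", {}).items()
        ] + [
            Parameter(name, "vmax", float(v))
            for name, v in raw.get("parameters", {}).get("vmax", {}).items()
        ]
        laws = [_parse_law(e) for e in raw["flux_laws"]]
        reactions = [
            Reaction(str(e["flux"]), {str(k): float(v) for k, v in e["stoich"].items()})
            for e in raw["reactions"]
        ]
    except (KeyError, TypeError) as exc:
        raise ModelValidationError(f"malformed model definition: {exc}") from exc

    return MetabolicModel(
        species=species,
        parameters=params,
        flux_laws=laws,
        reactions=reactions,
        observation_order=raw.get("observation_order", ()),
        auxiliary_outputs=raw.get("auxiliary_outputs", ()),
        name=str(raw.get("name", "model")),
    )


def evaluate_flux(
    law: FluxLaw, concentrations: Mapping[str, float], params: ParameterSet
) -> float:
    """Evaluate one Michaelis-Menten law at a concentration assignment.

    Returns ``vmax * prod [S]/(Km+[S])`` for irreversible laws and the
    forward minus reverse product for reversible ones (mM/h).
    """

    def product(vmax_name: str, terms: Iterable[tuple[str, str]]) -> float:
        out = params[vmax_name]
        for sid, km_name in terms:
            if sid not in concentrations:
                raise KeyError(f"flux law {law.id!r}: missing concentration for {sid!r}")
            c = concentrations[sid]
            if c < 0:
                raise ValueError(
                    f"flux law {law.id!r}: negative concentration for {sid!r}: {c}"
                )
            out *= c / (params[km_name] + c)
        return out

    v = product(law.forward_vmax, law.forward_terms)
    if law.reversible:
        v -= product(law.reverse_vmax, law.reverse_terms)
    return v


def assemble_rates(
    model: MetabolicModel,
    concentrations: Mapping[str, float],
    params: ParameterSet,
) -> dict[str, float]:
    """Net production rate (mM/h) of every state, S @ v at one state.

    Species untouched by any reaction get rate 0.
    """
    state = np.zeros(model.n_states)
    for sid, c in concentrations.items():
        if c < 0:
            raise ValueError(f"negative concentration for {sid!r}: {c}")
        state[model.species_index[sid]] = c
    missing = [
        sid
        for law in model.flux_laws
        for sid, _ in (*law.forward_terms, *law.reverse_terms)
        if sid not in concentrations
    ]
    if missing:
        raise KeyError(f"missing concentration(s): {sorted(set(missing))}")
    km, vmax = model._param_arrays(params)
    rates = model.rates(state, km, vmax)
    return dict(zip(model.state_ids, rates.tolist()))


def count_parameters(model: MetabolicModel) -> dict[str, int]:
    """Parameter census: Km, vmax, kinetic (= Km + vmax), initial
    concentrations, and their grand total."""
    n_km = len(model.km_names)
    n_vmax = len(model.vmax_names)
    n_initial = model.n_species
    return {
        "n_Km": n_km,
        "n_vmax": n_vmax,
        "n_kinetic": n_km + n_vmax,
        "n_initial": n_initial,
        "n_total": n_km + n_vmax + n_initial,
    }
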