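"""Reaction-network model representation and the model-document formats.

A :class:`ReactionNetworkModel` is the unit of work every parallel job
simulates: a set of chemical species (amounts in particle numbers), a set of
mass-action reactions whose rate constants are named model parameters, and a
compartment volume.  Two on-disk representations are supported:

* a native structured-text document (``[species]`` / ``[parameters]`` /
  ``[reactions]`` / ``[volume]`` sections) that job documents embed, and
* a reader for a subset of SBML Level 3 core (species, compartments,
  mass-action kinetic laws with a single rate parameter).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from lxml import etree

__all__ = [
    "Reaction",
    "ReactionNetworkModel",
    "Trajectory",
    "ModelValidationError",
    "read_native_model",
    "write_native_model",
    "read_sbml_model",
]


class ModelValidationError(ValueError):
    """Raised when a model document violates a structural invariant."""


_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction.

    ``reactants`` and ``products`` map species names to positive integer
    stoichiometric coefficients; ``rate_constant`` names the model parameter
    holding the rate constant.
    """

    reactants: dict[str, int]
    products: dict[str, int]
    rate_constant: str
    name: str = ""

    @property
    def order(self) -> int:
        return sum(self.reactants.values())


@dataclass
class ReactionNetworkModel:
    """Species, mass-action reactions and named parameters.

    ``species`` maps species name -> initial amount (particle numbers, >= 0);
    iteration order of the dict fixes the species order used everywhere
    downstream (trajectories, TSV columns, collation).
    """

    species: dict[str, float]
    reactions: list[Reaction]
    parameters: dict[str, float]
    volume: float = 1.0
    name: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.species:
            raise ModelValidationError("model has no species")
        for sp, amount in self.species.items():
            if not _NAME_RE.match(sp):
                raise ModelValidationError(f"invalid species name {sp!r}")
            if not np.isfinite(amount) or amount < 0:
                raise ModelValidationError(
                    f"initial amount of {sp!r} must be finite and >= 0, got {amount}"
                )
        for pname, value in self.parameters.items():
            if not _NAME_RE.match(pname):
                raise ModelValidationError(f"invalid parameter name {pname!r}")
            if not np.isfinite(value):
                raise ModelValidationError(f"parameter {pname!r} is not finite")
        if set(self.species) & set(self.parameters):
            clash = sorted(set(self.species) & set(self.parameters))
            raise ModelValidationError(f"names used as both species and parameter: {clash}")
        if not (np.isfinite(self.volume) and self.volume > 0):
            raise ModelValidationError(f"volume must be positive, got {self.volume}")
        for rxn in self.reactions:
            for side in (rxn.reactants, rxn.products):
                for sp, coeff in side.items():
                    if sp not in self.species:
                        raise ModelValidationError(
                            f"reaction {rxn.name!r} references unknown species {sp!r}"
                        )
                    if not (isinstance(coeff, (int, np.integer)) and coeff > 0):
                        raise ModelValidationError(
                            f"stoichiometric coefficient for {sp!r} must be a "
                            f"positive integer, got {coeff!r}"
                        )
            if rxn.rate_constant not in self.parameters:
                raise ModelValidationError(
                    f"reaction {rxn.name!r} rate constant {rxn.rate_constant!r} "
                    "does not resolve to a parameter"
                )

    @property
    def species_names(self) -> list[str]:
        return list(self.species)

    def initial_state(self) -> np.ndarray:
        return np.array(list(self.species.values()), dtype=float)

    def with_parameters(self, updates: dict[str, float]) -> "ReactionNetworkModel":
        """Return a copy with some parameter values replaced."""
        unknown = set(updates) - set(self.parameters)
        if unknown:
            raise ModelValidationError(f"unknown parameters: {sorted(unknown)}")
        params = dict(self.parameters)
        params.update(updates)
        return replace(self, parameters=params, species=dict(self.species),
                       reactions=list(self.reactions))


@dataclass
class Trajectory:
    """Time-course output on a uniform grid.

    ``values`` has shape ``(len(time_grid), len(species))`` and holds amounts
    in particle numbers.  ``time_grid[0]`` is always 0.
    """

    time_grid: np.ndarray
    values: np.ndarray
    species: list[str]

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_grid.ndim != 1 or self.time_grid[0] != 0.0:
            raise ValueError("time grid must be 1-D and start at 0")
        if np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.values.shape != (len(self.time_grid), len(self.species)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.time_grid)} time points x {len(self.species)} species"
            )

    def to_tsv(self, path) -> None:
        """Write the standard time-course dialect: 'Time' column then one
        column per species, tab-separated."""
        header = "Time\t" + "\t".join(self.species)
        data = np.column_stack([self.time_grid, self.values])
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for row in data:
                fh.write("\t".join(format(x, ".10g") for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "Trajectory":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            rows = [list(map(float, line.split("\t"))) for line in fh if line.strip()]
        if header[0] != "Time":
            raise ValueError(f"expected first column 'Time', got {header[0]!r}")
        data = np.array(rows, dtype=float)
        return cls(time_grid=data[:, 0], values=data[:, 1:], species=header[1:])


# ---------------------------------------------------------------------------
# Native model document
# ---------------------------------------------------------------------------

def _format_side(side: dict[str, int]) -> str:
    if not side:
        return ""
    return " + ".join(f"{c} {s}" if c != 1 else s for s, c in side.items())


def _parse_side(text: str) -> dict[str, int]:
    side: dict[str, int] = {}
    text = text.strip()
    if not text:
        return side
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ModelValidationError(f"empty term in reaction side {text!r}")
        parts = term.split()
        if len(parts) == 1:
            coeff, sp = 1, parts[0]
        elif len(parts) == 2:
            coeff, sp = int(parts[0]), parts[1]
        else:
            raise ModelValidationError(f"cannot parse reaction term {term!r}")
        side[sp] = side.get(sp, 0) + coeff
    return side


def write_native_model(model: ReactionNetworkModel) -> str:
    """Serialize to the native structured-text document."""
    lines = [f"# model {model.name}", "[species]"]
    for sp, amount in model.species.items():
        lines.append(f"{sp} = {amount:.10g}")
    lines.append("[parameters]")
    for pname, value in model.parameters.items():
        lines.append(f"{pname} = {value:.10g}")
    lines.append("[reactions]")
    for i, rxn in enumerate(model.reactions):
        name = rxn.name or f"r{i}"
        lines.append(
            f"{name}: {_format_side(rxn.reactants)} -> "
            f"{_format_side(rxn.products)} ; {rxn.rate_constant}"
        )
    lines.append("[volume]")
    lines.append(f"{model.volume:.10g}")
    return "\n".join(lines) + "\n"


def read_native_model(text: str) -> ReactionNetworkModel:
    """Parse the native structured-text document back into a model."""
    name = "model"
    section = None
    species: dict[str, float] = {}
    parameters: dict[str, float] = {}
    reactions: list[Reaction] = []
    volume = 1.0
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*model\s+(\S+)", line)
            if m:
                name = m.group(1)
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            continue
        if section == "species":
            key, _, val = line.partition("=")
            species[key.strip()] = float(val)
        elif section == "parameters":
            key, _, val = line.partition("=")
            parameters[key.strip()] = float(val)
        elif section == "reactions":
            rname, _, rest = line.partition(":")
            body, _, rate = rest.partition(";")
            lhs, arrow, rhs = body.partition("->")
            if not arrow:
                raise ModelValidationError(f"reaction line missing '->': {line!r}")
            reactions.append(
                Reaction(
                    reactants=_parse_side(lhs),
                    products=_parse_side(rhs),
                    rate_constant=rate.strip(),
                    name=rname.strip(),
                )
            )
        elif section == "volume":
            volume = float(line)
        else:
            raise ModelValidationError(f"line outside any section: {line!r}")
    return ReactionNetworkModel(
        species=species, reactions=reactions, parameters=parameters,
        volume=volume, name=name,
    )


# ---------------------------------------------------------------------------
# SBML Level 3 core subset reader
# ---------------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def read_sbml_model(source) -> ReactionNetworkModel:
    """Read an SBML Level 3 core document restricted to mass-action kinetics.

    Supported constructs: one compartment (its size becomes the volume),
    species with ``initialAmount``, global parameters, and reactions whose
    kinetic law is a MathML product of a single rate parameter and the
    reactant species (any power).  Anything else raises
    :class:`ModelValidationError`.
    """
    tree = etree.parse(source) if not hasattr(source, "getroot") else source
    root = tree.getroot()
    ns = {"s": _SBML_NS, "m": _MATHML_NS}
    model_el = root.find("s:model", ns)
    if model_el is None:
        raise ModelValidationError("no <model> element found")

    volume = 1.0
    compartments = model_el.findall("s:listOfCompartments/s:compartment", ns)
    if len(compartments) > 1:
        raise ModelValidationError("only single-compartment models supported")
    if compartments and compartments[0].get("size") is not None:
        volume = float(compartments[0].get("size"))

    species: dict[str, float] = {}
    for sp in model_el.findall("s:listOfSpecies/s:species", ns):
        amount = sp.get("initialAmount")
        if amount is None:
            raise ModelValidationError(
                f"species {sp.get('id')!r} lacks initialAmount (subset requires amounts)"
            )
        species[sp.get("id")] = float(amount)

    parameters: dict[str, float] = {}
    for par in model_el.findall("s:listOfParameters/s:parameter", ns):
        parameters[par.get("id")] = float(par.get("value"))

    reactions: list[Reaction] = []
    for rxn in model_el.findall("s:listOfReactions/s:reaction", ns):
        reactants: dict[str, int] = {}
        products: dict[str, int] = {}
        for ref in rxn.findall("s:listOfReactants/s:speciesReference", ns):
            reactants[ref.get("species")] = int(float(ref.get("stoichiometry", "1")))
        for ref in rxn.findall("s:listOfProducts/s:speciesReference", ns):
            products[ref.get("species")] = int(float(ref.get("stoichiometry", "1")))
        rate_param = _extract_rate_parameter(rxn, reactants, parameters, ns)
        reactions.append(
            Reaction(reactants=reactants, products=products,
                     rate_constant=rate_param, name=rxn.get("id") or "")
        )
    return ReactionNetworkModel(
        species=species, reactions=reactions, parameters=parameters,
        volume=volume, name=model_el.get("id") or "sbml_model",
    )


def _extract_rate_parameter(rxn, reactants, parameters, ns) -> str:
    """The kinetic law must be k * product(reactant species); return k."""
    math = rxn.find("s:kineticLaw/m:math", ns)
    if math is None:
        raise ModelValidationError(f"reaction {rxn.get('id')!r} has no kinetic law")
    names = [el.text.strip() for el in math.iter(f"{{{_MATHML_NS}}}ci")]
    param_names = [n for n in names if n in parameters]
    if len(param_names) != 1:
        raise ModelValidationError(
            f"reaction {rxn.get('id')!r}: kinetic law must reference exactly one "
            f"rate parameter, found {param_names}"
        )
    non_params = [n for n in names if n not in parameters]
    if set(non_params) - set(reactants):
        raise ModelValidationError(
            f"reaction {rxn.get('id')!r}: kinetic law references species "
            f"{sorted(set(non_params) - set(reactants))} that are not reactants "
            "(not mass action)"
        )
    return param_names[0]
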