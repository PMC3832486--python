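"""Reaction-network model objects and the plain-text model description language.

A :class:`Model` is an ordered list of :class:`Species` plus an ordered list
of :class:`Reaction` objects and a parameter table.  State is always integer
copy numbers; species order fixes the state-vector index convention.

Rate laws come in two flavours:

* mass action — a single rate constant ``c``; the propensity carries the
  Gillespie combinatorial factor (``c·n`` for A, ``c·nA·nB`` for A+B,
  ``c·n(n−1)/2`` for 2A, in general ``c·∏ C(n_i, m_i)``),
* expression — an arbitrary arithmetic expression over species copy numbers
  and parameters, evaluated by a restricted interpreter.

Species whose name is declared with a ``$`` prefix are *fixed* (buffered):
they participate in propensities but are never changed by reaction firings.
The reserved token ``$pool`` denotes the empty set in reaction equations.

MDL grammar (one statement per line, ``#`` starts a comment)::

    species line:    <name> = <integer>          ($ prefix marks fixed species)
    parameter line:  <name> : <real>
    reaction line:   <rname>: <reactants> > <products>, <rate>

where reactants/products are "+"-separated ``coef*name`` terms (coefficient
optional, default 1) or ``$pool`` for the empty set, and ``<rate>`` is a bare
numeric constant (mass action) or an arithmetic expression.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .expressions import ExpressionError, RateExpression

__all__ = [
    "Species",
    "MassAction",
    "Reaction",
    "Model",
    "ModelError",
    "MdlSyntaxError",
    "parse_mdl",
    "write_mdl",
    "compute_propensity",
]

POOL = "$pool"

_IDENT = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class ModelError(ValueError):
    """Semantic model error: undefined identifier, negative amount, duplicate name."""


class MdlSyntaxError(ModelError):
    """MDL text does not conform to the grammar; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Species:
    """A molecular species tracked as an integer copy number."""

    name: str
    initial_copies: int
    fixed: bool = False
    partition_at_division: bool = True

    def __post_init__(self):
        if not _IDENT.match(self.name):
            raise ModelError(f"invalid species name {self.name!r}")
        n = self.initial_copies
        if n != int(n) or n < 0:
            raise ModelError(
                f"species {self.name!r}: initial copy number must be a "
                f"non-negative integer, got {n!r}"
            )
        object.__setattr__(self, "initial_copies", int(n))


@dataclass(frozen=True)
class MassAction:
    """Mass-action rate law with a single stochastic rate constant.

    Units: time⁻¹ for zero/first order, per-reactant-pair time⁻¹ for second
    order.
    """

    constant: float

    def __post_init__(self):
        if self.constant < 0:
            raise ModelError(f"negative mass-action rate constant {self.constant}")


RateLaw = MassAction | RateExpression


@dataclass(frozen=True)
class Reaction:
    """A reaction with reactant/product multiplicities and a rate law.

    ``reactants``/``products`` map species names to positive integer
    multiplicities; fixed species may appear on either side but are never
    updated by a firing.
    """

    name: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_law: RateLaw

    def __post_init__(self):
        if not _IDENT.match(self.name):
            raise ModelError(f"invalid reaction name {self.name!r}")
        for side, label in ((self.reactants, "reactant"), (self.products, "product")):
            for sp, mult in side.items():
                if mult != int(mult) or mult <= 0:
                    raise ModelError(
                        f"reaction {self.name!r}: {label} {sp!r} multiplicity "
                        f"must be a positive integer, got {mult!r}"
                    )
        if not self.reactants and not self.products:
            raise ModelError(
                f"reaction {self.name!r}: at least one of reactants/products "
                "must be non-empty"
            )
        object.__setattr__(self, "reactants", dict(self.reactants))
        object.__setattr__(self, "products", dict(self.products))

    @property
    def order(self) -> int | None:
        """Total reactant multiplicity; None for expression rate laws."""
        return sum(self.reactants.values())

    def net_change(self) -> dict[str, int]:
        """Net stoichiometric change: products − reactants (all species)."""
        net: dict[str, int] = {}
        for sp, m in self.products.items():
            net[sp] = net.get(sp, 0) + m
        for sp, m in self.reactants.items():
            net[sp] = net.get(sp, 0) - m
        return {sp: v for sp, v in net.items() if v != 0}


@dataclass
class Model:
    """A simulable reaction network.

    The species list order fixes state-vector indexing; ``initial_state()``
    returns the integer copy-number vector in that order.
    """

    species: Sequence[Species]
    reactions: Sequence[Reaction]
    parameters: Mapping[str, float] = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self):
        self.species = list(self.species)
        self.reactions = list(self.reactions)
        self.parameters = dict(self.parameters)
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ModelError(f"duplicate species name {dup!r}")
        rnames = [r.name for r in self.reactions]
        if len(set(rnames)) != len(rnames):
            dup = next(n for n in rnames if rnames.count(n) > 1)
            raise ModelError(f"duplicate reaction name {dup!r}")
        known = set(names) | set(self.parameters)
        clash = set(names) & set(self.parameters)
        if clash:
            raise ModelError(f"name {sorted(clash)[0]!r} is both species and parameter")
        for r in self.reactions:
            for sp in list(r.reactants) + list(r.products):
                if sp not in set(names):
                    raise ModelError(
                        f"reaction {r.name!r} references undeclared species {sp!r}"
                    )
            if isinstance(r.rate_law, RateExpression):
                try:
                    r.rate_law.check_resolvable(known)
                except ExpressionError as exc:
                    raise ModelError(f"reaction {r.name!r}: {exc}") from exc

    @property
    def species_names(self) -> list[str]:
        return [sp.name for sp in self.species]

    @property
    def reaction_names(self) -> list[str]:
        return [r.name for r in self.reactions]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise ModelError(f"unknown species {name!r}") from None

    def reaction_index(self, name: str) -> int:
        try:
            return self.reaction_names.index(name)
        except ValueError:
            raise ModelError(f"unknown reaction {name!r}") from None

    def initial_state(self) -> np.ndarray:
        return np.array([sp.initial_copies for sp in self.species], dtype=np.int64)

    def with_initial_state(self, state: Sequence[int]) -> "Model":
        """A copy of the model whose species start at *state*."""
        state = np.asarray(state)
        if len(state) != len(self.species):
            raise ModelError("state length does not match species count")
        new_species = [
            replace(sp, initial_copies=int(n)) for sp, n in zip(self.species, state)
        ]
        return Model(new_species, self.reactions, self.parameters, self.name)

    def net_stoichiometry(self) -> np.ndarray:
        """(n_reactions, n_species) net-change matrix; fixed species rows are 0."""
        idx = {sp.name: i for i, sp in enumerate(self.species)}
        fixed = {sp.name for sp in self.species if sp.fixed}
        nu = np.zeros((len(self.reactions), len(self.species)), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            for sp, v in r.net_change().items():
                if sp not in fixed:
                    nu[j, idx[sp]] = v
        return nu

    def compile(self) -> "CompiledModel":
        return CompiledModel(self)

    # -- semantic equality (used by round-trip tests) ----------------------

    def semantically_equal(self, other: "Model") -> bool:
        if self.species_names != other.species_names:
            return False
        if [(s.initial_copies, s.fixed) for s in self.species] != [
            (s.initial_copies, s.fixed) for s in other.species
        ]:
            return False
        if self.parameters != other.parameters:
            return False
        if len(self.reactions) != len(other.reactions):
            return False
        for a, b in zip(self.reactions, other.reactions):
            if (a.name, a.reactants, a.products) != (b.name, b.reactants, b.products):
                return False
            if type(a.rate_law) is not type(b.rate_law):
                return False
            if isinstance(a.rate_law, MassAction):
                if a.rate_law.constant != b.rate_law.constant:
                    return False
            elif a.rate_law.text.replace(" ", "") != b.rate_law.text.replace(" ", ""):
                return False
        return True


class CompiledModel:
    """Propensity evaluator and stoichiometry tables for fast simulation."""

    def __init__(self, model: Model):
        self.model = model
        self.n_species = len(model.species)
        self.n_reactions = len(model.reactions)
        self.net = model.net_stoichiometry()
        idx = {sp.name: i for i, sp in enumerate(model.species)}
        self._names = model.species_names
        self._params = dict(model.parameters)
        # per reaction: ("ma", c, [(species_idx, mult), ...]) or ("expr", fn, var_idx)
        self._progs = []
        for r in model.reactions:
            if isinstance(r.rate_law, MassAction):
                pairs = [(idx[sp], m) for sp, m in sorted(r.reactants.items())]
                self._progs.append(("ma", float(r.rate_law.constant), pairs))
            else:
                self._progs.append(("expr", r.rate_law, None))
        # species whose count each reaction's propensity reads
        self.read_sets: list[frozenset[int]] = []
        for r in model.reactions:
            if isinstance(r.rate_law, MassAction):
                self.read_sets.append(frozenset(idx[sp] for sp in r.reactants))
            else:
                self.read_sets.append(
                    frozenset(idx[v] for v in r.rate_law.variables if v in idx)
                )

    def propensity(self, j: int, state: np.ndarray) -> float:
        kind, payload, pairs = self._progs[j]
        if kind == "ma":
            a = payload
            for i, m in pairs:
                n = state[i]
                if m == 1:
                    a *= n
                elif m == 2:
                    a *= n * (n - 1) / 2.0
                else:
                    a *= math.comb(int(n), m)
                if a == 0.0:
                    return 0.0
            return float(a)
        env = dict(self._params)
        for i, name in enumerate(self._names):
            env[name] = float(state[i])
        val = payload(env)
        if val < 0:
            warnings.warn(
                f"rate expression {payload.text!r} evaluated negative "
                f"({val:g}); clipped to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            return 0.0
        return val

    def propensities(self, state: np.ndarray, out: np.ndarray | None = None) -> np.ndarray:
        if out is None:
            out = np.empty(self.n_reactions)
        for j in range(self.n_reactions):
            out[j] = self.propensity(j, state)
        return out


def compute_propensity(
    reaction: Reaction, state: Mapping[str, int], parameters: Mapping[str, float]
) -> float:
    """Propensity of a single reaction at a named state (convenience API).

    *state* maps species names to copy numbers; all species referenced by the
    reaction must be present and non-negative.
    """
    for sp, n in state.items():
        if n < 0:
            raise ModelError(f"negative copy number for {sp!r}")
    if isinstance(reaction.rate_law, MassAction):
        a = reaction.rate_law.constant
        for sp, m in reaction.reactants.items():
            if sp not in state:
                raise ModelError(f"state does not define species {sp!r}")
            n = int(state[sp])
            a *= math.comb(n, m)
        return float(a)
    env = {**parameters, **{k: float(v) for k, v in state.items()}}
    val = reaction.rate_law(env)
    if val < 0:
        warnings.warn(
            f"rate expression {reaction.rate_law.text!r} evaluated negative; clipped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return val


# ---------------------------------------------------------------------------
# MDL parsing / writing
# ---------------------------------------------------------------------------


def _parse_side(text: str, lineno: int) -> dict[str, int]:
    """Parse a '+'-separated reactant or product list; $pool → empty."""
    text = text.strip()
    if not text:
        raise MdlSyntaxError("empty reaction side", lineno)
    out: dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        if term == POOL:
            continue
        coef = 1
        if "*" in term:
            coef_s, _, name = term.partition("*")
            try:
                coef = int(coef_s.strip())
            except ValueError:
                raise MdlSyntaxError(
                    f"invalid stoichiometric coefficient {coef_s.strip()!r}", lineno
                ) from None
            term = name.strip()
        if term.startswith("$"):
            term = term[1:]
        if not _IDENT.match(term):
            raise MdlSyntaxError(f"invalid species reference {term!r}", lineno)
        out[term] = out.get(term, 0) + coef
    return out


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def parse_mdl(text: str, name: str = "model") -> Model:
    """Parse model-description text into a validated :class:`Model`.

    Statements may appear in any order (reactions may precede the species
    declarations they reference).  Raises :class:`MdlSyntaxError` with a line
    number on bad syntax and :class:`ModelError` on semantic problems.
    """
    species: list[Species] = []
    reactions: list[Reaction] = []
    parameters: dict[str, float] = {}
    saw_statement = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        saw_statement = True
        if ">" in line:  # reaction line
            head, _, rest = line.partition(":")
            rname = head.strip()
            if not rest or not _IDENT.match(rname):
                raise MdlSyntaxError(f"malformed reaction statement {line!r}", lineno)
            eq, comma, rate_s = rest.rpartition(",")
            if not comma or not eq.strip():
                raise MdlSyntaxError(
                    "reaction line must be '<name>: <reactants> > <products>, <rate>'",
                    lineno,
                )
            lhs, gt, rhs = eq.partition(">")
            if not gt:
                raise MdlSyntaxError("missing '>' in reaction equation", lineno)
            reactants = _parse_side(lhs, lineno)
            products = _parse_side(rhs, lineno)
            rate_s = rate_s.strip()
            if not rate_s:
                raise MdlSyntaxError("missing rate", lineno)
            rate_law: RateLaw
            if _is_number(rate_s):
                rate_law = MassAction(float(rate_s))
            else:
                try:
                    rate_law = RateExpression(rate_s)
                except ExpressionError as exc:
                    raise MdlSyntaxError(str(exc), lineno) from exc
            try:
                reactions.append(Reaction(rname, reactants, products, rate_law))
            except ModelError as exc:
                raise MdlSyntaxError(str(exc), lineno) from exc
        elif "=" in line:  # species line
            lhs, _, rhs = line.partition("=")
            spname = lhs.strip()
            fixed = spname.startswith("$")
            if fixed:
                spname = spname[1:]
            if not _IDENT.match(spname):
                raise MdlSyntaxError(f"invalid species name {spname!r}", lineno)
            rhs = rhs.strip()
            try:
                amount = float(rhs)
            except ValueError:
                raise MdlSyntaxError(f"invalid initial amount {rhs!r}", lineno) from None
            if amount < 0:
                raise MdlSyntaxError(
                    f"negative initial amount for species {spname!r}", lineno
                )
            if amount != int(amount):
                raise MdlSyntaxError(
                    f"non-integer initial amount {rhs} for species {spname!r}", lineno
                )
            species.append(Species(spname, int(amount), fixed=fixed))
        elif ":" in line:  # parameter line
            lhs, _, rhs = line.partition(":")
            pname = lhs.strip()
            if not _IDENT.match(pname):
                raise MdlSyntaxError(f"invalid parameter name {pname!r}", lineno)
            try:
                parameters[pname] = float(rhs.strip())
            except ValueError:
                raise MdlSyntaxError(
                    f"invalid parameter value {rhs.strip()!r}", lineno
                ) from None
        else:
            raise MdlSyntaxError(f"unrecognized statement {line!r}", lineno)

    if not saw_statement:
        raise MdlSyntaxError("empty model description")
    return Model(species, reactions, parameters, name=name)


def _side_to_text(side: Mapping[str, int], fixed: set[str]) -> str:
    if not side:
        return POOL
    terms = []
    for sp, m in side.items():
        ref = f"${sp}" if sp in fixed else sp
        terms.append(ref if m == 1 else f"{m}*{ref}")
    return " + ".join(terms)


def write_mdl(model: Model) -> str:
    """Serialize a model to MDL text; ``parse_mdl`` on the result returns a
    semantically identical model."""
    fixed = {sp.name for sp in model.species if sp.fixed}
    lines = [f"# model: {model.name}"]
    for pname, val in model.parameters.items():
        lines.append(f"{pname} : {val!r}")
    for r in model.reactions:
        rate = (
            repr(r.rate_law.constant)
            if isinstance(r.rate_law, MassAction)
            else r.rate_law.text
        )
        lines.append(
            f"{r.name}: {_side_to_text(r.reactants, fixed)} > "
            f"{_side_to_text(r.products, fixed)}, {rate}"
        )
    for sp in model.species:
        prefix = "$" if sp.fixed else ""
        lines.append(f"{prefix}{sp.name} = {sp.initial_copies}")
    return "\n".join(lines) + "\n"
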