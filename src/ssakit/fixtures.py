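"""Built-in case-study models.

Four reaction networks ship with the package as MDL files:

* ``immigration_death`` — constitutive synthesis (10 min⁻¹) + first-order
  decay (0.2 min⁻¹); stationary law Poisson(50).
* ``two_state_gene`` — telegraph gene; ``bursty`` (default) and
  ``non_bursty`` parameter sets (package defaults, overridable).
* ``single_enzyme`` — single-molecule Michaelis–Menten cycle;
  ``clamped`` (buffered substrate, default) and ``consumable`` variants.
* ``tx_tl_division`` — nine-reaction transcription–translation network with
  one saturating non-mass-action rate law, for cell-division studies.

Only the immigration-death constants are published values; the remaining
parameter sets are documented package defaults chosen to realize the
qualitative regimes they are named for (see ``documented_parameters``
provenance tags and docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .model import Model, parse_mdl

__all__ = ["FixtureModel", "FIXTURE_NAMES", "build_fixture", "fixture_mdl_text"]

FIXTURE_NAMES = (
    "immigration_death",
    "two_state_gene",
    "single_enzyme",
    "tx_tl_division",
)

_VARIANTS = {
    "immigration_death": (None,),
    "two_state_gene": ("bursty", "non_bursty"),
    "single_enzyme": ("clamped", "consumable"),
    "tx_tl_division": (None,),
}

# value, provenance tag
_DOCS = {
    "immigration_death": {
        "ksyn": (10.0, "published (min^-1)"),
        "kd": (0.2, "published (min^-1)"),
    },
    "two_state_gene:bursty": {
        "kon": (0.01, "package default (min^-1): long OFF dwell"),
        "koff": (0.01, "package default (min^-1): long ON dwell"),
        "ksyn": (1.0, "package default (min^-1)"),
        "kd": (0.05, "package default (min^-1)"),
    },
    "two_state_gene:non_bursty": {
        "kon": (1.0, "package default (min^-1): short OFF dwell"),
        "koff": (1.0, "package default (min^-1): short ON dwell"),
        "ksyn": (1.0, "package default (min^-1)"),
        "kd": (0.05, "package default (min^-1)"),
    },
    "single_enzyme:clamped": {
        "k1*S": (1.0, "package default (min^-1), substrate buffered at 100"),
        "km1": (0.5, "package default (min^-1)"),
        "k2": (1.0, "package default (min^-1)"),
    },
    "single_enzyme:consumable": {
        "k1": (0.01, "package default (per pair min^-1)"),
        "km1": (0.5, "package default (min^-1)"),
        "k2": (1.0, "package default (min^-1)"),
        "S0": (100, "package default (copies)"),
    },
    "tx_tl_division": {
        "vmax": (2.0, "package default (min^-1), saturating transcription"),
        "Km": (2.0, "package default (copies)"),
        "division_shape": (1.0, "published (gamma shape)"),
        "division_scale": (60.0, "published (gamma scale, min)"),
    },
}


@dataclass(frozen=True)
class FixtureModel:
    """A fully parameterized case-study model with parameter provenance."""

    name: str
    variant: str | None
    model: Model
    documented_parameters: dict


def fixture_mdl_text(name: str) -> str:
    """Raw MDL text of a shipped fixture file."""
    if name not in FIXTURE_NAMES and name != "single_enzyme_consumable":
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return (resources.files("ssakit") / "data" / f"{name}.mdl").read_text()


def build_fixture(name: str, variant: str | None = None) -> FixtureModel:
    """Construct a shipped case-study model by name.

    ``two_state_gene`` accepts variant ``"bursty"`` (default) or
    ``"non_bursty"``; ``single_enzyme`` accepts ``"clamped"`` (default) or
    ``"consumable"``.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    allowed = _VARIANTS[name]
    if variant is None:
        variant = allowed[0]
    if variant not in allowed:
        raise KeyError(f"fixture {name!r} has no variant {variant!r} (choose {allowed})")

    if name == "single_enzyme" and variant == "consumable":
        model = parse_mdl(fixture_mdl_text("single_enzyme_consumable"),
                          name="single_enzyme_consumable")
    else:
        model = parse_mdl(fixture_mdl_text(name), name=name)
    if name == "two_state_gene" and variant == "non_bursty":
        params = dict(model.parameters, kon=1.0, koff=1.0)
        model = Model(model.species, model.reactions, params,
                      name="two_state_gene_non_bursty")
    doc_key = f"{name}:{variant}" if f"{name}:{variant}" in _DOCS else name
    return FixtureModel(name, variant, model, dict(_DOCS[doc_key]))
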