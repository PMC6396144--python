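"""SBML Level 3 Version 1 export / import of TAF models.

A :class:`~tafsim.models.ModelSpec` is flattened into a mass-action
reaction network over species ``C_0 .. C_cap`` (cells indexed by TAF
count, truncated at the cap) and ``NF`` (the pooled non-telomeric focus
count).  The compound-Poisson division increment, which SBML cannot
express natively, is unrolled into finitely many channels
``C_k -> C_{k+j}`` with rate constants ``delta_c * pmf(j; mu_d)``,
truncated where the omitted Poisson tail mass falls below 1e-6.  All
kinetic laws are products of a constant and the reactant amount, so any
standard stochastic simulator can run the document.

Documents produced here are recognised on import by their parameter
naming convention and reconstructed exactly; any other document is parsed
into a :class:`ForeignModelReport` (species, reactions, parameters) and
never silently coerced into a ModelSpec.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from scipy.stats import poisson

from .models import MECHANISMS, ModelSpec

__all__ = [
    "SbmlDocumentRef",
    "ForeignModelReport",
    "export_sbml",
    "import_sbml",
    "validate_sbml",
    "SbmlParseError",
]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
_DIVISION_TAIL = 1e-6
_SPEC_PARAMS = (
    "lambda_T", "delta_c", "mu_d", "lambda_N", "rho",
    "horizon_months", "n_cells", "taf_cap", "initial_mean_taf",
)


class SbmlParseError(ValueError):
    """Raised on malformed or non-SBML XML."""


@dataclass
class SbmlDocumentRef:
    content: str
    model_id: str
    annotations: str | None = None  # e.g. a BioModels accession


@dataclass
class ForeignModelReport:
    """Structured description of an SBML model outside this convention."""

    model_id: str
    species: list = field(default_factory=list)  # (id, initial_amount)
    reactions: list = field(default_factory=list)  # (id, reactants, products, rate_constant, rate_species)
    parameters: dict = field(default_factory=dict)


def _q(tag: str) -> str:
    return f"{{{SBML_NS}}}{tag}"


def _mq(tag: str) -> str:
    return f"{{{MATHML_NS}}}{tag}"


def _mass_action_math(parent, factors):
    """Attach <math><apply><times/> ci... </apply></math> (or single <ci>)."""
    math_el = ET.SubElement(parent, _mq("math"))
    if len(factors) == 1:
        ET.SubElement(math_el, _mq("ci")).text = f" {factors[0]} "
        return
    apply_el = ET.SubElement(math_el, _mq("apply"))
    ET.SubElement(apply_el, _mq("times"))
    for f in factors:
        ET.SubElement(apply_el, _mq("ci")).text = f" {f} "


def _add_reaction(list_el, rid, reactants, products, rate_factors):
    r = ET.SubElement(list_el, _q("reaction"), id=rid, reversible="false")
    if reactants:
        lo = ET.SubElement(r, _q("listOfReactants"))
        for sp in reactants:
            ET.SubElement(
                lo, _q("speciesReference"),
                species=sp, stoichiometry="1", constant="true",
            )
    if products:
        lo = ET.SubElement(r, _q("listOfProducts"))
        for sp in products:
            ET.SubElement(
                lo, _q("speciesReference"),
                species=sp, stoichiometry="1", constant="true",
            )
    kl = ET.SubElement(r, _q("kineticLaw"))
    _mass_action_math(kl, rate_factors)


def export_sbml(model: ModelSpec, annotations: str | None = None) -> SbmlDocumentRef:
    """Encode a ModelSpec as an SBML L3V1 mass-action network."""
    cap = model.taf_cap
    # initial cell mass distributed over TAF classes (Poisson at time 0)
    if model.initial_mean_taf > 0:
        pmf = poisson.pmf(range(cap + 1), model.initial_mean_taf)
        truncated = 1.0 - float(pmf.sum())
        if truncated > 0.01:
            raise ValueError(
                f"taf_cap {cap} would truncate {truncated:.1%} of the "
                "initial TAF distribution"
            )
        init_amounts = [model.n_cells * float(p) for p in pmf]
        init_amounts[cap] += model.n_cells * truncated
    else:
        init_amounts = [0.0] * (cap + 1)
        init_amounts[0] = float(model.n_cells)
    nf0 = model.n_cells * (model.lambda_N / model.rho) if model.rho > 0 else 0.0

    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    root = ET.Element(_q("sbml"), level="3", version="1")
    model_id = f"taf_{model.mechanism}"
    mdl = ET.Element(_q("model"), id=model_id, name="TAF accumulation model")
    root.append(mdl)
    if annotations:
        ann = ET.SubElement(mdl, _q("annotation"))
        ann.text = annotations

    lc = ET.SubElement(mdl, _q("listOfCompartments"))
    ET.SubElement(
        lc, _q("compartment"), id="cell_population", size="1",
        spatialDimensions="3", constant="true",
    )

    ls = ET.SubElement(mdl, _q("listOfSpecies"))
    for k in range(cap + 1):
        ET.SubElement(
            ls, _q("species"), id=f"C_{k}", compartment="cell_population",
            initialAmount=repr(init_amounts[k]),
            hasOnlySubstanceUnits="true",
            boundaryCondition="false", constant="false",
        )
    ET.SubElement(
        ls, _q("species"), id="NF", compartment="cell_population",
        initialAmount=repr(nf0), hasOnlySubstanceUnits="true",
        boundaryCondition="false", constant="false",
    )

    lp = ET.SubElement(mdl, _q("listOfParameters"))
    for name in _SPEC_PARAMS:
        ET.SubElement(
            lp, _q("parameter"), id=name,
            value=repr(float(getattr(model, name))), constant="true",
        )

    lr = ET.SubElement(mdl, _q("listOfReactions"))
    if model.lambda_T > 0:
        for k in range(cap):
            _add_reaction(
                lr, f"taf_gain_{k}", [f"C_{k}"], [f"C_{k + 1}"],
                ["lambda_T", f"C_{k}"],
            )
    if model.delta_c > 0 and model.mu_d > 0:
        # unroll Poisson(mu_d) increments; drop j = 0 (no state change)
        j_max = int(poisson.ppf(1.0 - _DIVISION_TAIL, model.mu_d)) + 1
        for j in range(1, j_max + 1):
            w = float(poisson.pmf(j, model.mu_d))
            if w <= 0:
                continue
            pid = f"k_div_{j}"
            ET.SubElement(
                lp, _q("parameter"), id=pid,
                value=repr(model.delta_c * w), constant="true",
            )
            for k in range(cap):
                _add_reaction(
                    lr, f"division_{k}_{j}", [f"C_{k}"],
                    [f"C_{min(k + j, cap)}"], [pid, f"C_{k}"],
                )
    if model.lambda_N > 0:
        _add_reaction(lr, "nontaf_gain", [], ["NF"], ["lambda_N", "n_cells"])
    if model.rho > 0:
        _add_reaction(lr, "nontaf_repair", ["NF"], [], ["rho", "NF"])

    ET.indent(root)
    content = ET.tostring(root, encoding="unicode", xml_declaration=True)
    return SbmlDocumentRef(content=content, model_id=model_id,
                           annotations=annotations)


def _parse_root(content: str):
    try:
        root = ET.fromstring(content)
    except ET.ParseError as exc:
        raise SbmlParseError(f"malformed XML: {exc}") from exc
    if root.tag != _q("sbml"):
        raise SbmlParseError(f"root element is not SBML L3V1: {root.tag}")
    mdl = root.find(_q("model"))
    if mdl is None:
        raise SbmlParseError("document has no <model> element")
    return root, mdl


def _math_factors(kl) -> list[str]:
    """Flatten a mass-action kineticLaw into its ci/cn factor names."""
    math_el = kl.find(_mq("math"))
    if math_el is None:
        return []
    factors = []

    def walk(el):
        tag = el.tag
        if tag == _mq("ci"):
            factors.append(el.text.strip())
        elif tag == _mq("cn"):
            factors.append(el.text.strip())
        else:
            for child in el:
                if child.tag != _mq("times"):
                    walk(child)

    walk(math_el)
    return factors


def _report_from_model(mdl) -> ForeignModelReport:
    species = [
        (s.get("id"), float(s.get("initialAmount", "0")))
        for s in mdl.iter(_q("species"))
    ]
    params = {
        p.get("id"): float(p.get("value", "nan"))
        for p in mdl.iter(_q("parameter"))
    }
    species_ids = {sid for sid, _ in species}
    reactions = []
    for r in mdl.iter(_q("reaction")):
        reactants = [
            sr.get("species")
            for lo in r.findall(_q("listOfReactants"))
            for sr in lo.findall(_q("speciesReference"))
        ]
        products = [
            sr.get("species")
            for lo in r.findall(_q("listOfProducts"))
            for sr in lo.findall(_q("speciesReference"))
        ]
        kl = r.find(_q("kineticLaw"))
        rate_constant = 1.0
        rate_species = []
        if kl is not None:
            for f in _math_factors(kl):
                if f in species_ids:
                    rate_species.append(f)
                elif f in params:
                    rate_constant *= params[f]
                else:
                    try:
                        rate_constant *= float(f)
                    except ValueError:
                        rate_constant = float("nan")
        reactions.append(
            (r.get("id"), reactants, products, rate_constant, rate_species)
        )
    return ForeignModelReport(
        model_id=mdl.get("id", ""),
        species=species,
        reactions=reactions,
        parameters=params,
    )


def import_sbml(doc: SbmlDocumentRef | str):
    """Reconstruct a ModelSpec from a document exported by this package.

    Returns a :class:`ForeignModelReport` when the document does not carry
    the expected parameter naming convention (e.g. an external BioModels
    deposit); raises :class:`SbmlParseError` on malformed XML.
    """
    content = doc.content if isinstance(doc, SbmlDocumentRef) else doc
    _, mdl = _parse_root(content)
    report = _report_from_model(mdl)
    mechanism = report.model_id.removeprefix("taf_")
    if mechanism not in MECHANISMS or not all(
        name in report.parameters for name in _SPEC_PARAMS
    ):
        return report
    p = report.parameters
    return ModelSpec(
        mechanism=mechanism,
        lambda_T=p["lambda_T"],
        delta_c=p["delta_c"],
        mu_d=p["mu_d"],
        lambda_N=p["lambda_N"],
        rho=p["rho"],
        horizon_months=p["horizon_months"],
        n_cells=int(p["n_cells"]),
        taf_cap=int(p["taf_cap"]),
        initial_mean_taf=p["initial_mean_taf"],
    )


def validate_sbml(doc: SbmlDocumentRef | str) -> list[str]:
    """Structural validation; returns a list of error messages (empty = valid).

    Checks the SBML L3V1 namespace and level/version, required id and
    compartment attributes, that every reaction carries a mass-action
    kinetic law referencing declared entities, and that every rate
    parameter is nonnegative.
    """
    content = doc.content if isinstance(doc, SbmlDocumentRef) else doc
    errors: list[str] = []
    try:
        root, mdl = _parse_root(content)
    except SbmlParseError as exc:
        return [str(exc)]
    if root.get("level") != "3" or root.get("version") != "1":
        errors.append("sbml element must declare level=3 version=1")
    if not mdl.get("id"):
        errors.append("model must have an id")

    compartments = {c.get("id") for c in mdl.iter(_q("compartment"))}
    species_ids = set()
    for s in mdl.iter(_q("species")):
        sid = s.get("id")
        if not sid:
            errors.append("species without id")
            continue
        species_ids.add(sid)
        if s.get("compartment") not in compartments:
            errors.append(f"species {sid} references unknown compartment")
        try:
            if float(s.get("initialAmount", "0")) < 0:
                errors.append(f"species {sid} has negative initialAmount")
        except ValueError:
            errors.append(f"species {sid} has non-numeric initialAmount")

    params = {}
    for p in mdl.iter(_q("parameter")):
        pid = p.get("id")
        if not pid:
            errors.append("parameter without id")
            continue
        try:
            params[pid] = float(p.get("value", "nan"))
        except ValueError:
            errors.append(f"parameter {pid} has non-numeric value")
            continue
        if not math.isfinite(params[pid]) or params[pid] < 0:
            errors.append(f"parameter {pid} must be finite and nonnegative")

    for r in mdl.iter(_q("reaction")):
        rid = r.get("id") or "<anonymous>"
        kl = r.find(_q("kineticLaw"))
        if kl is None:
            errors.append(f"reaction {rid} has no kineticLaw")
            continue
        factors = _math_factors(kl)
        if not factors:
            errors.append(f"reaction {rid} kineticLaw has no rate expression")
        reactants = {
            sr.get("species")
            for lo in r.findall(_q("listOfReactants"))
            for sr in lo.findall(_q("speciesReference"))
        }
        for f in factors:
            if f in species_ids:
                if f not in reactants and f != "n_cells":
                    # species factor must be a reactant for mass action
                    errors.append(
                        f"reaction {rid} rate references non-reactant species {f}"
                    )
            elif f not in params:
                try:
                    float(f)
                except ValueError:
                    errors.append(f"reaction {rid} rate references unknown symbol {f}")
    return errors
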