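"""LEMS document object model: ComponentTypes, Components, XML I/O, validation.

A LEMS document declares dimensions and units, prototypes (``ComponentType``)
carrying parameters, exposures, event ports and a ``Dynamics`` state machine,
and parameterized instances (``Component``).  Types compose through a
prototype-extension mechanism (``extends``) and through containment
(``Child``/``Children`` specs).

The XML reader is deliberately order-tolerant: elements may appear in any
order inside their parent, but containment rules are enforced -- a
``<StateVariable>`` outside ``<Dynamics>`` is a structural error, not noise.
The structural schema is encoded as an internal containment table rather than
an external XSD, so the rules are self-contained and directly testable.

Component parameter values are kept as their original quantity text until
resolve time, so unit errors can be reported with the user's own spelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .errors import (
    Issue,
    ParseError,
    StructureError,
    UnitError,
    UnresolvedReferenceError,
    ValidationError,
    has_errors,
)
from . import expressions
from .units import (
    DIMENSIONLESS,
    Dimension,
    Quantity,
    Unit,
    UnitRegistry,
    builtin_registry,
    check_dimension,
    parse_quantity,
)

__all__ = [
    "LemsModel",
    "ComponentType",
    "Component",
    "Dynamics",
    "StateAssignment",
    "ResolvedComponent",
    "load_lems",
    "write_lems",
    "flatten_type",
    "validate_lems",
    "resolve_component",
]


# --------------------------------------------------------------------------
# Object model


@dataclass
class Parameter:
    name: str
    dimension: str


@dataclass
class Exposure:
    name: str
    dimension: str


@dataclass
class Requirement:
    name: str
    dimension: str


@dataclass
class ChildSpec:
    role: str
    type: str
    multiple: bool


@dataclass
class EventPort:
    name: str
    direction: str  # "in" | "out"


@dataclass
class StateVariable:
    name: str
    dimension: str
    exposure: str | None = None


@dataclass
class DerivedVariable:
    name: str
    value: str
    exposure: str | None = None


@dataclass
class TimeDerivative:
    variable: str
    value: str


@dataclass
class StateAssignment:
    variable: str
    value: str


@dataclass
class EventHandler:
    """OnStart / OnCondition / OnEvent body.

    ``test`` is set for OnCondition, ``port`` for OnEvent, neither for
    OnStart.
    """

    assignments: list[StateAssignment] = field(default_factory=list)
    event_outs: list[str] = field(default_factory=list)
    test: str | None = None
    port: str | None = None


@dataclass
class Dynamics:
    state_variables: list[StateVariable] = field(default_factory=list)
    derived_variables: list[DerivedVariable] = field(default_factory=list)
    time_derivatives: list[TimeDerivative] = field(default_factory=list)
    on_start: list[EventHandler] = field(default_factory=list)
    on_conditions: list[EventHandler] = field(default_factory=list)
    on_events: list[EventHandler] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (
            self.state_variables
            or self.derived_variables
            or self.time_derivatives
            or self.on_start
            or self.on_conditions
            or self.on_events
        )


@dataclass
class ComponentType:
    name: str
    extends: str | None = None
    parameters: list[Parameter] = field(default_factory=list)
    exposures: list[Exposure] = field(default_factory=list)
    requirements: list[Requirement] = field(default_factory=list)
    children_specs: list[ChildSpec] = field(default_factory=list)
    event_ports: list[EventPort] = field(default_factory=list)
    dynamics: Dynamics = field(default_factory=Dynamics)


@dataclass
class Component:
    id: str
    type: str
    parameter_values: dict[str, str] = field(default_factory=dict)
    children: list["Component"] = field(default_factory=list)


@dataclass
class Constant:
    name: str
    dimension: str
    value: str


@dataclass
class LemsModel:
    dimensions: list[Dimension] = field(default_factory=list)
    units: list[Unit] = field(default_factory=list)
    constants: list[Constant] = field(default_factory=list)
    component_types: dict[str, ComponentType] = field(default_factory=dict)
    components: dict[str, Component] = field(default_factory=dict)
    target: str | None = None

    def registry(self) -> UnitRegistry:
        """Builtin registry overlaid with the document's own dimensions/units."""
        reg = builtin_registry()
        for dim in self.dimensions:
            reg.add_dimension(dim)
        for unit in self.units:
            reg.add_unit(unit)
        return reg


# --------------------------------------------------------------------------
# XML reading

# element -> allowed child elements.  Anything structural found outside its
# allowed parent is a StructureError; unknown tags under Lems / Component are
# treated as typed component shorthand.
_CONTAINMENT = {
    "Lems": {"Dimension", "Unit", "Constant", "ComponentType", "Component", "Target"},
    "ComponentType": {
        "Parameter",
        "Exposure",
        "Requirement",
        "Child",
        "Children",
        "EventPort",
        "Dynamics",
    },
    "Dynamics": {
        "StateVariable",
        "DerivedVariable",
        "TimeDerivative",
        "OnStart",
        "OnCondition",
        "OnEvent",
    },
    "OnStart": {"StateAssignment", "EventOut"},
    "OnCondition": {"StateAssignment", "EventOut"},
    "OnEvent": {"StateAssignment", "EventOut"},
}

_STRUCTURAL = set(_CONTAINMENT) | set().union(*_CONTAINMENT.values())

_DIM_LETTERS = ("m", "l", "t", "i", "k", "n", "j")


def _attr(element, name, default=None, required=False):
    value = element.get(name, default)
    if required and value is None:
        raise ParseError(
            f"<{element.tag}> missing required attribute {name!r}"
        )
    return value


def _check_containment(parent_tag, element):
    tag = element.tag
    allowed = _CONTAINMENT.get(parent_tag, set())
    if tag in allowed:
        return "structural"
    if tag in _STRUCTURAL:
        raise StructureError(
            f"<{tag}> is not allowed inside <{parent_tag}>"
        )
    return "component"


def load_lems(source) -> LemsModel:
    """Load a LEMS document from a path or from XML text.

    Element order inside a parent is irrelevant; containment violations
    raise :class:`StructureError`; malformed XML raises :class:`ParseError`.
    """
    root = _parse_xml(source)
    if root.tag != "Lems":
        raise StructureError(f"root element must be <Lems>, got <{root.tag}>")
    model = LemsModel()
    for child in _iter_elements(root):
        kind = _check_containment("Lems", child)
        tag = child.tag
        if kind == "component" or tag == "Component":
            comp = _read_component(child)
            if comp.id in model.components:
                raise StructureError(f"duplicate component id {comp.id!r}")
            model.components[comp.id] = comp
        elif tag == "Dimension":
            exps = {
                letter: int(child.get(letter, "0")) for letter in _DIM_LETTERS
            }
            model.dimensions.append(Dimension(_attr(child, "name", required=True), **exps))
        elif tag == "Unit":
            model.units.append(
                Unit(
                    _attr(child, "symbol", required=True),
                    _attr(child, "dimension", required=True),
                    int(_attr(child, "power", "0")),
                )
            )
        elif tag == "Constant":
            model.constants.append(
                Constant(
                    _attr(child, "name", required=True),
                    _attr(child, "dimension", DIMENSIONLESS),
                    _attr(child, "value", required=True),
                )
            )
        elif tag == "ComponentType":
            ctype = _read_component_type(child)
            model.component_types[ctype.name] = ctype
        elif tag == "Target":
            model.target = _attr(child, "component", required=True)
    return model


def _parse_xml(source):
    try:
        if isinstance(source, (str, Path)) and "\n" not in str(source) and Path(str(source)).exists():
            tree = etree.parse(str(source))
            return tree.getroot()
        text = source if isinstance(source, (str, bytes)) else str(source)
        if isinstance(text, str):
            text = text.encode("utf-8")
        return etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from None


def _iter_elements(element):
    for child in element:
        if isinstance(child.tag, str):  # skip comments / PIs
            yield child


def _read_component_type(element) -> ComponentType:
    ctype = ComponentType(
        name=_attr(element, "name", required=True),
        extends=element.get("extends"),
    )
    for child in _iter_elements(element):
        _check_containment("ComponentType", child)
        tag = child.tag
        if tag == "Parameter":
            ctype.parameters.append(
                Parameter(_attr(child, "name", required=True), _attr(child, "dimension", DIMENSIONLESS))
            )
        elif tag == "Exposure":
            ctype.exposures.append(
                Exposure(_attr(child, "name", required=True), _attr(child, "dimension", DIMENSIONLESS))
            )
        elif tag == "Requirement":
            ctype.requirements.append(
                Requirement(_attr(child, "name", required=True), _attr(child, "dimension", DIMENSIONLESS))
            )
        elif tag == "Child":
            ctype.children_specs.append(
                ChildSpec(_attr(child, "name", required=True), _attr(child, "type", required=True), False)
            )
        elif tag == "Children":
            ctype.children_specs.append(
                ChildSpec(_attr(child, "name", required=True), _attr(child, "type", required=True), True)
            )
        elif tag == "EventPort":
            ctype.event_ports.append(
                EventPort(_attr(child, "name", required=True), _attr(child, "direction", required=True))
            )
        elif tag == "Dynamics":
            ctype.dynamics = _read_dynamics(child)
    return ctype


def _read_dynamics(element) -> Dynamics:
    dyn = Dynamics()
    for child in _iter_elements(element):
        _check_containment("Dynamics", child)
        tag = child.tag
        if tag == "StateVariable":
            dyn.state_variables.append(
                StateVariable(
                    _attr(child, "name", required=True),
                    _attr(child, "dimension", DIMENSIONLESS),
                    child.get("exposure"),
                )
            )
        elif tag == "DerivedVariable":
            dyn.derived_variables.append(
                DerivedVariable(
                    _attr(child, "name", required=True),
                    _attr(child, "value", required=True),
                    child.get("exposure"),
                )
            )
        elif tag == "TimeDerivative":
            dyn.time_derivatives.append(
                TimeDerivative(_attr(child, "variable", required=True), _attr(child, "value", required=True))
            )
        elif tag == "OnStart":
            dyn.on_start.append(_read_handler(child))
        elif tag == "OnCondition":
            handler = _read_handler(child)
            handler.test = _attr(child, "test", required=True)
            dyn.on_conditions.append(handler)
        elif tag == "OnEvent":
            handler = _read_handler(child)
            handler.port = _attr(child, "port", required=True)
            dyn.on_events.append(handler)
    return dyn


def _read_handler(element) -> EventHandler:
    handler = EventHandler()
    for child in _iter_elements(element):
        _check_containment(element.tag, child)
        if child.tag == "StateAssignment":
            handler.assignments.append(
                StateAssignment(_attr(child, "variable", required=True), _attr(child, "value", required=True))
            )
        elif child.tag == "EventOut":
            handler.event_outs.append(_attr(child, "port", required=True))
    return handler


def _read_component(element) -> Component:
    if element.tag == "Component":
        comp_id = _attr(element, "id", required=True)
        comp_type = _attr(element, "type", required=True)
        skip = {"id", "type"}
    else:
        comp_id = _attr(element, "id", required=True)
        comp_type = element.tag
        skip = {"id"}
    comp = Component(id=comp_id, type=comp_type)
    for key, value in element.attrib.items():
        if key not in skip:
            comp.parameter_values[key] = value
    for child in _iter_elements(element):
        if child.tag != "Component" and child.tag in _STRUCTURAL:
            raise StructureError(f"<{child.tag}> is not allowed inside a component")
        comp.children.append(_read_component(child))
    return comp


# --------------------------------------------------------------------------
# XML writing


def write_lems(model: LemsModel) -> str:
    """Serialize to canonical LEMS XML (UTF-8 text, 4-space indent).

    The model must validate first; ``load_lems(write_lems(m))`` is
    semantically equal to ``m`` (canonical trees, not byte equality).
    """
    issues = validate_lems(model)
    if has_errors(issues):
        raise ValidationError("model does not validate", issues)

    root = etree.Element("Lems")
    for dim in model.dimensions:
        el = etree.SubElement(root, "Dimension", name=dim.name)
        for letter in _DIM_LETTERS:
            value = getattr(dim, letter)
            if value:
                el.set(letter, str(value))
    for unit in model.units:
        etree.SubElement(
            root, "Unit", symbol=unit.symbol, dimension=unit.dimension, power=str(unit.power)
        )
    for const in model.constants:
        etree.SubElement(
            root, "Constant", name=const.name, dimension=const.dimension, value=const.value
        )
    for ctype in model.component_types.values():
        _write_component_type(root, ctype)
    for comp in model.components.values():
        _write_component(root, comp)
    if model.target is not None:
        etree.SubElement(root, "Target", component=model.target)
    etree.indent(root, space="    ")
    return etree.tostring(root, encoding="unicode") + "\n"


def _write_component_type(parent, ctype: ComponentType):
    attrs = {"name": ctype.name}
    if ctype.extends:
        attrs["extends"] = ctype.extends
    el = etree.SubElement(parent, "ComponentType", **attrs)
    for p in ctype.parameters:
        etree.SubElement(el, "Parameter", name=p.name, dimension=p.dimension)
    for e in ctype.exposures:
        etree.SubElement(el, "Exposure", name=e.name, dimension=e.dimension)
    for r in ctype.requirements:
        etree.SubElement(el, "Requirement", name=r.name, dimension=r.dimension)
    for c in ctype.children_specs:
        tag = "Children" if c.multiple else "Child"
        etree.SubElement(el, tag, name=c.role, type=c.type)
    for port in ctype.event_ports:
        etree.SubElement(el, "EventPort", name=port.name, direction=port.direction)
    if not ctype.dynamics.is_empty():
        dyn = etree.SubElement(el, "Dynamics")
        for sv in ctype.dynamics.state_variables:
            attrs = {"name": sv.name, "dimension": sv.dimension}
            if sv.exposure:
                attrs["exposure"] = sv.exposure
            etree.SubElement(dyn, "StateVariable", **attrs)
        for dv in ctype.dynamics.derived_variables:
            attrs = {"name": dv.name, "value": dv.value}
            if dv.exposure:
                attrs["exposure"] = dv.exposure
            etree.SubElement(dyn, "DerivedVariable", **attrs)
        for td in ctype.dynamics.time_derivatives:
            etree.SubElement(dyn, "TimeDerivative", variable=td.variable, value=td.value)
        for handler in ctype.dynamics.on_start:
            _write_handler(dyn, "OnStart", handler)
        for handler in ctype.dynamics.on_conditions:
            _write_handler(dyn, "OnCondition", handler)
        for handler in ctype.dynamics.on_events:
            _write_handler(dyn, "OnEvent", handler)


def _write_handler(parent, tag, handler: EventHandler):
    attrs = {}
    if handler.test is not None:
        attrs["test"] = handler.test
    if handler.port is not None:
        attrs["port"] = handler.port
    el = etree.SubElement(parent, tag, **attrs)
    for sa in handler.assignments:
        etree.SubElement(el, "StateAssignment", variable=sa.variable, value=sa.value)
    for port in handler.event_outs:
        etree.SubElement(el, "EventOut", port=port)


def _write_component(parent, comp: Component):
    # canonical form: typed shorthand element named after the component type
    el = etree.SubElement(parent, comp.type, id=comp.id)
    for key, value in comp.parameter_values.items():
        el.set(key, value)
    for child in comp.children:
        _write_component(el, child)


# --------------------------------------------------------------------------
# Type flattening


def flatten_type(model: LemsModel, type_name: str) -> ComponentType:
    """Merge a type's extension chain into a single self-contained type.

    The derived type overrides its base on name collision (parameters,
    exposures, requirements, event ports, children specs, state/derived
    variables and time derivatives are keyed by name; handler lists
    concatenate, base first).  Idempotent: flattening a flattened type is
    the identity.
    """
    chain = []
    seen = set()
    name = type_name
    while name is not None:
        if name in seen:
            raise StructureError(f"extension cycle through {name!r}")
        seen.add(name)
        ctype = model.component_types.get(name)
        if ctype is None:
            raise UnresolvedReferenceError(f"unknown ComponentType {name!r}")
        chain.append(ctype)
        name = ctype.extends
    if len(chain) == 1:
        return chain[0]

    merged = ComponentType(name=type_name, extends=None)
    for ctype in reversed(chain):  # base first, derived overrides
        _merge_keyed(merged.parameters, ctype.parameters, lambda x: x.name)
        _merge_keyed(merged.exposures, ctype.exposures, lambda x: x.name)
        _merge_keyed(merged.requirements, ctype.requirements, lambda x: x.name)
        _merge_keyed(merged.children_specs, ctype.children_specs, lambda x: x.role)
        _merge_keyed(merged.event_ports, ctype.event_ports, lambda x: x.name)
        dyn = ctype.dynamics
        _merge_keyed(merged.dynamics.state_variables, dyn.state_variables, lambda x: x.name)
        _merge_keyed(merged.dynamics.derived_variables, dyn.derived_variables, lambda x: x.name)
        _merge_keyed(merged.dynamics.time_derivatives, dyn.time_derivatives, lambda x: x.variable)
        merged.dynamics.on_start.extend(dyn.on_start)
        merged.dynamics.on_conditions.extend(dyn.on_conditions)
        merged.dynamics.on_events.extend(dyn.on_events)
    return merged


def _merge_keyed(target, source, key):
    index = {key(item): pos for pos, item in enumerate(target)}
    for item in source:
        k = key(item)
        if k in index:
            target[index[k]] = item
        else:
            index[k] = len(target)
            target.append(item)


# --------------------------------------------------------------------------
# Validation


def validate_lems(model: LemsModel) -> list[Issue]:
    """Structural validation; returns issues as data (empty list == valid)."""
    issues: list[Issue] = []

    try:
        registry = model.registry()
    except UnitError as exc:
        issues.append(Issue("error", str(exc)))
        registry = builtin_registry()

    # constants
    constant_names = set()
    for const in model.constants:
        constant_names.add(const.name)
        _check_quantity(const.value, const.dimension, registry, f"Constant {const.name}", issues)

    # component types
    for name, ctype in model.component_types.items():
        loc = f"ComponentType {name}"
        if ctype.extends is not None and ctype.extends not in model.component_types:
            issues.append(Issue("error", f"unresolved extends {ctype.extends!r}", loc))
            continue
        try:
            flat = flatten_type(model, name)
        except StructureError as exc:
            issues.append(Issue("error", str(exc), loc))
            continue
        # shadowing between derived and base is legal but worth noting
        base_names = set()
        chain_type = model.component_types.get(ctype.extends) if ctype.extends else None
        while chain_type is not None:
            base_names.update(p.name for p in chain_type.parameters)
            chain_type = model.component_types.get(chain_type.extends) if chain_type.extends else None
        for p in ctype.parameters:
            if p.name in base_names:
                issues.append(
                    Issue("info", f"parameter {p.name!r} overrides an inherited definition", loc)
                )
        _validate_dynamics(flat, registry, constant_names, loc, issues)

    # components
    for comp_id, comp in model.components.items():
        _validate_component(model, comp, registry, issues)

    if model.target is not None and model.target not in model.components:
        issues.append(Issue("error", f"target component {model.target!r} does not exist"))
    return issues


def _check_quantity(text, dimension, registry, location, issues) -> None:
    try:
        q = parse_quantity(text, registry)
    except (ParseError, UnitError) as exc:
        issues.append(Issue("error", str(exc), location))
        return
    if dimension not in registry.dimensions:
        issues.append(Issue("error", f"unknown dimension {dimension!r}", location))
    elif not check_dimension(q, dimension, registry):
        issues.append(
            Issue(
                "error",
                f"value {text!r} does not match dimension {dimension!r}",
                location,
            )
        )


def _validate_dynamics(flat: ComponentType, registry, constant_names, loc, issues):
    dyn = flat.dynamics
    state_names = {sv.name for sv in dyn.state_variables}
    derived_names = {dv.name for dv in dyn.derived_variables}
    known = (
        state_names
        | derived_names
        | {p.name for p in flat.parameters}
        | {r.name for r in flat.requirements}
        | constant_names
        | {"t"}
    )

    for dim_name in [sv.dimension for sv in dyn.state_variables] + [
        p.dimension for p in flat.parameters
    ]:
        if dim_name not in registry.dimensions:
            issues.append(Issue("error", f"unknown dimension {dim_name!r}", loc))

    def check_expr(text, where, boolean=False):
        try:
            tree = expressions.parse_expr(text)
        except ParseError as exc:
            issues.append(Issue("error", f"{where}: {exc}", loc))
            return
        for ident in sorted(expressions.free_variables(tree)):
            if ident not in known:
                issues.append(Issue("error", f"{where}: unbound identifier {ident!r}", loc))

    for td in dyn.time_derivatives:
        if td.variable not in state_names:
            issues.append(
                Issue("error", f"TimeDerivative targets non-state {td.variable!r}", loc)
            )
        check_expr(td.value, f"d{td.variable}/dt")
    for dv in dyn.derived_variables:
        check_expr(dv.value, f"DerivedVariable {dv.name}")
    for handler_list, kind in (
        (dyn.on_start, "OnStart"),
        (dyn.on_conditions, "OnCondition"),
        (dyn.on_events, "OnEvent"),
    ):
        for handler in handler_list:
            if handler.test is not None:
                check_expr(handler.test, f"{kind} test")
            for sa in handler.assignments:
                if sa.variable not in state_names:
                    issues.append(
                        Issue(
                            "error",
                            f"{kind} assigns to non-state {sa.variable!r}",
                            loc,
                        )
                    )
                check_expr(sa.value, f"{kind} assignment to {sa.variable}")
            out_ports = {p.name for p in flat.event_ports if p.direction == "out"}
            for port in handler.event_outs:
                if port not in out_ports:
                    issues.append(Issue("error", f"{kind} emits unknown port {port!r}", loc))
            if handler.port is not None:
                in_ports = {p.name for p in flat.event_ports if p.direction == "in"}
                if handler.port not in in_ports:
                    issues.append(
                        Issue("error", f"OnEvent listens on unknown port {handler.port!r}", loc)
                    )

    # derived-variable dependency graph must be acyclic
    try:
        _derived_order(dyn)
    except StructureError as exc:
        issues.append(Issue("error", str(exc), loc))


def _derived_order(dyn: Dynamics) -> list[DerivedVariable]:
    """Topological order of derived variables (dependencies first)."""
    by_name = {dv.name: dv for dv in dyn.derived_variables}
    deps = {}
    for dv in dyn.derived_variables:
        try:
            free = expressions.free_variables(expressions.parse_expr(dv.value))
        except ParseError:
            free = set()
        deps[dv.name] = {f for f in free if f in by_name}
    order: list[DerivedVariable] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(name):
        if state.get(name) == 1:
            return
        if state.get(name) == 0:
            raise StructureError(f"cyclic derived variables through {name!r}")
        state[name] = 0
        for dep in sorted(deps[name]):
            visit(dep)
        state[name] = 1
        order.append(by_name[name])

    for dv in dyn.derived_variables:
        visit(dv.name)
    return order


def _validate_component(model, comp: Component, registry, issues, path=""):
    loc = f"Component {path}{comp.id}"
    if comp.type not in model.component_types:
        issues.append(Issue("error", f"unknown type {comp.type!r}", loc))
        return
    try:
        flat = flatten_type(model, comp.type)
    except (StructureError, UnresolvedReferenceError) as exc:
        issues.append(Issue("error", str(exc), loc))
        return
    declared = {p.name: p for p in flat.parameters}
    for pname, ptype in declared.items():
        if pname not in comp.parameter_values:
            issues.append(Issue("error", f"missing value for parameter {pname!r}", loc))
    for pname, text in comp.parameter_values.items():
        if pname not in declared:
            issues.append(Issue("warning", f"value for undeclared parameter {pname!r}", loc))
            continue
        _check_quantity(text, declared[pname].dimension, registry, loc, issues)
    # children conformance
    spec_by_type: dict[str, ChildSpec] = {spec.type: spec for spec in flat.children_specs}
    counts: dict[str, int] = {}
    for child in comp.children:
        spec = spec_by_type.get(child.type)
        if spec is None:
            issues.append(
                Issue("warning", f"child {child.id!r} of type {child.type!r} not in children specs", loc)
            )
        else:
            counts[spec.type] = counts.get(spec.type, 0) + 1
            if not spec.multiple and counts[spec.type] > 1:
                issues.append(
                    Issue("error", f"multiple children of single-child type {child.type!r}", loc)
                )
        _validate_component(model, child, registry, issues, path=f"{path}{comp.id}/")


# --------------------------------------------------------------------------
# Resolution


@dataclass
class ResolvedComponent:
    """A component with its flattened type and every parameter as an SI real."""

    id: str
    type: ComponentType
    parameters: dict[str, float]
    children: list["ResolvedComponent"] = field(default_factory=list)


def resolve_component(model: LemsModel, component_id: str) -> ResolvedComponent:
    """Flatten the type and convert every parameter value to SI units.

    Children resolve recursively (depth-first).  Raises
    :class:`UnresolvedReferenceError` / :class:`UnitError` on dangling
    references or unit mismatches.
    """
    comp = model.components.get(component_id)
    if comp is None:
        raise UnresolvedReferenceError(f"unknown component {component_id!r}")
    registry = model.registry()
    return _resolve(model, comp, registry)


def _resolve(model, comp: Component, registry) -> ResolvedComponent:
    if comp.type not in model.component_types:
        raise UnresolvedReferenceError(
            f"component {comp.id!r} has unknown type {comp.type!r}"
        )
    flat = flatten_type(model, comp.type)
    declared = {p.name: p for p in flat.parameters}
    values: dict[str, float] = {}
    for pname, param in declared.items():
        text = comp.parameter_values.get(pname)
        if text is None:
            raise UnitError(f"component {comp.id!r}: missing parameter {pname!r}")
        q = parse_quantity(text, registry)
        if not check_dimension(q, param.dimension, registry):
            raise UnitError(
                f"component {comp.id!r}: {pname}={text!r} does not match "
                f"dimension {param.dimension!r}"
            )
        values[pname] = q.si_value
    children = [_resolve(model, child, registry) for child in comp.children]
    return ResolvedComponent(id=comp.id, type=flat, parameters=values, children=children)


def resolved_constants(model: LemsModel) -> dict[str, float]:
    """Document-level constants as SI reals."""
    registry = model.registry()
    return {c.name: parse_quantity(c.value, registry).si_value for c in model.constants}


# --------------------------------------------------------------------------
# Semantic equality (for round-trip checks)


def canonical_form(model: LemsModel):
    """A nested, order-normalized structure for semantic comparison."""

    def quantity_key(text, registry):
        try:
            q = parse_quantity(text, registry)
            return (q.si_value, q.unit is not None)
        except (ParseError, UnitError):
            return text

    registry = model.registry()

    def comp_form(comp: Component):
        return (
            comp.id,
            comp.type,
            tuple(sorted((k, quantity_key(v, registry)) for k, v in comp.parameter_values.items())),
            tuple(sorted((comp_form(c) for c in comp.children))),
        )

    def ctype_form(ct: ComponentType):
        dyn = ct.dynamics
        return (
            ct.name,
            ct.extends,
            tuple(sorted((p.name, p.dimension) for p in ct.parameters)),
            tuple(sorted((e.name, e.dimension) for e in ct.exposures)),
            tuple(sorted((r.name, r.dimension) for r in ct.requirements)),
            tuple(sorted((c.role, c.type, c.multiple) for c in ct.children_specs)),
            tuple(sorted((p.name, p.direction) for p in ct.event_ports)),
            tuple(sorted((sv.name, sv.dimension, sv.exposure or "") for sv in dyn.state_variables)),
            tuple(sorted((dv.name, dv.value, dv.exposure or "") for dv in dyn.derived_variables)),
            tuple(sorted((td.variable, td.value) for td in dyn.time_derivatives)),
            tuple(_handler_form(h) for h in dyn.on_start),
            tuple(_handler_form(h) for h in dyn.on_conditions),
            tuple(_handler_form(h) for h in dyn.on_events),
        )

    def _handler_form(h: EventHandler):
        return (
            h.test,
            h.port,
            tuple((sa.variable, sa.value) for sa in h.assignments),
            tuple(h.event_outs),
        )

    return (
        tuple(sorted((d.name, d.exponents()) for d in model.dimensions)),
        tuple(sorted((u.symbol, u.dimension, u.power) for u in model.units)),
        tuple(sorted((c.name, c.dimension, quantity_key(c.value, registry)) for c in model.constants)),
        tuple(sorted(ctype_form(ct) for ct in model.component_types.values())),
        tuple(sorted(comp_form(c) for c in model.components.values())),
        model.target,
    )
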