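"""Hand-written LEMS/NeuroML fixture documents.

These small documents exercise the whole stack: a leaky-decay state (closed
form available, used for convergence checks), the two-variable Izhikevich
spiking cell with its threshold/reset rule, a two-exponential synapse built
on a ``baseSynapse`` prototype (type extension + event ports), and the
three-variable Hindmarsh-Rose burster whose derivatives are shortened
through derived variables.

The spiking fixtures keep their classic dimensionless equations but stay
dimensionally honest by scaling through document constants ``MVOLT`` (1 mV)
and ``MSEC`` (1 ms): voltages are genuine voltages, and the classic
"per millisecond" dynamics integrate correctly in SI seconds.
"""

from __future__ import annotations

from .lems import LemsModel, load_lems
from .serialization import loads_neuroml_xml
from .synth import NetGenSpec, build_random_network

__all__ = [
    "LEMS_LEAKY_DECAY",
    "LEMS_IZHIKEVICH",
    "LEMS_HINDMARSH_ROSE",
    "LEMS_SYNAPSE",
    "NEUROML_TWO_SEGMENT_XML",
    "SWC_TOY",
    "leaky_decay_model",
    "izhikevich_model",
    "hindmarsh_rose_model",
    "synapse_model",
    "two_segment_document",
    "example_network_document",
]


LEMS_LEAKY_DECAY = """\
<Lems>
    <ComponentType name="leakyDecay">
        <Parameter name="tau" dimension="time"/>
        <Parameter name="v0" dimension="none"/>
        <Exposure name="v" dimension="none"/>
        <Dynamics>
            <StateVariable name="v" dimension="none" exposure="v"/>
            <TimeDerivative variable="v" value="-v / tau"/>
            <OnStart>
                <StateAssignment variable="v" value="v0"/>
            </OnStart>
        </Dynamics>
    </ComponentType>
    <leakyDecay id="decay" tau="10ms" v0="1"/>
    <Target component="decay"/>
</Lems>
"""

# Classic regular-spiking parameterization; I is the constant drive of the
# dimensionless equations and v0 the initial membrane potential.
LEMS_IZHIKEVICH = """\
<Lems>
    <Constant name="MVOLT" dimension="voltage" value="1mV"/>
    <Constant name="MSEC" dimension="time" value="1ms"/>
    <Constant name="Iext" dimension="none" value="10"/>
    <ComponentType name="izhikevichCell">
        <Parameter name="a" dimension="none"/>
        <Parameter name="b" dimension="none"/>
        <Parameter name="c" dimension="voltage"/>
        <Parameter name="d" dimension="none"/>
        <Parameter name="thresh" dimension="voltage"/>
        <Exposure name="v" dimension="voltage"/>
        <EventPort name="spike" direction="out"/>
        <Dynamics>
            <StateVariable name="v" dimension="voltage" exposure="v"/>
            <StateVariable name="U" dimension="none"/>
            <DerivedVariable name="vr" value="v / MVOLT"/>
            <TimeDerivative variable="v" value="(0.04 * vr^2 + 5 * vr + 140 - U + Iext) * MVOLT / MSEC"/>
            <TimeDerivative variable="U" value="a * (b * vr - U) / MSEC"/>
            <OnStart>
                <StateAssignment variable="v" value="c"/>
                <StateAssignment variable="U" value="b * c / MVOLT"/>
            </OnStart>
            <OnCondition test="v .gt. thresh">
                <StateAssignment variable="v" value="c"/>
                <StateAssignment variable="U" value="U + d"/>
                <EventOut port="spike"/>
            </OnCondition>
        </Dynamics>
    </ComponentType>
    <izhikevichCell id="izhRS" a="0.02" b="0.2" c="-65mV" d="8" thresh="30mV"/>
    <Target component="izhRS"/>
</Lems>
"""

# Three state variables (x, y, z), eight fixed parameters; time derivatives
# are shortened through derived variables.  Parameters sit in the classic
# square-wave bursting regime.
LEMS_HINDMARSH_ROSE = """\
<Lems>
    <Constant name="MSEC" dimension="time" value="1ms"/>
    <ComponentType name="hindmarshRoseCell">
        <Parameter name="a" dimension="none"/>
        <Parameter name="b" dimension="none"/>
        <Parameter name="c" dimension="none"/>
        <Parameter name="d" dimension="none"/>
        <Parameter name="r" dimension="none"/>
        <Parameter name="s" dimension="none"/>
        <Parameter name="x1" dimension="none"/>
        <Parameter name="Iamp" dimension="none"/>
        <Exposure name="x" dimension="none"/>
        <Dynamics>
            <StateVariable name="x" dimension="none" exposure="x"/>
            <StateVariable name="y" dimension="none"/>
            <StateVariable name="z" dimension="none"/>
            <DerivedVariable name="phi" value="b * x^2 - a * x^3"/>
            <DerivedVariable name="chi" value="c - d * x^2"/>
            <TimeDerivative variable="x" value="(y + phi - z + Iamp) / MSEC"/>
            <TimeDerivative variable="y" value="(chi - y) / MSEC"/>
            <TimeDerivative variable="z" value="r * (s * (x - x1) - z) / MSEC"/>
            <OnStart>
                <StateAssignment variable="x" value="x1"/>
                <StateAssignment variable="y" value="c - d * x1^2"/>
            </OnStart>
        </Dynamics>
    </ComponentType>
    <hindmarshRoseCell id="hr" a="1" b="3" c="1" d="5" r="0.003" s="4" x1="-1.6" Iamp="2.7"/>
    <Target component="hr"/>
</Lems>
"""

# Two-exponential conductance synapse as an extension of a baseSynapse
# prototype; incoming events increment both exponential relaxations.
LEMS_SYNAPSE = """\
<Lems>
    <ComponentType name="baseSynapse">
        <Exposure name="g" dimension="conductance"/>
        <EventPort name="in" direction="in"/>
    </ComponentType>
    <ComponentType name="expTwoSynapse" extends="baseSynapse">
        <Parameter name="gbase" dimension="conductance"/>
        <Parameter name="erev" dimension="voltage"/>
        <Parameter name="tauRise" dimension="time"/>
        <Parameter name="tauDecay" dimension="time"/>
        <Dynamics>
            <StateVariable name="A" dimension="none"/>
            <StateVariable name="B" dimension="none"/>
            <DerivedVariable name="g" value="gbase * (B - A)" exposure="g"/>
            <TimeDerivative variable="A" value="-A / tauRise"/>
            <TimeDerivative variable="B" value="-B / tauDecay"/>
            <OnEvent port="in">
                <StateAssignment variable="A" value="A + 1"/>
                <StateAssignment variable="B" value="B + 1"/>
            </OnEvent>
        </Dynamics>
    </ComponentType>
    <expTwoSynapse id="syn" gbase="1nS" erev="0mV" tauRise="0.5ms" tauDecay="2ms"/>
</Lems>
"""


NEUROML_TWO_SEGMENT_XML = """\
<?xml version="1.0" encoding="UTF-8"?>
<neuroml id="two_segment_cell">
    <morphology id="simple_morphology">
        <segment id="0" name="soma">
            <proximal x="0" y="0" z="0" diameter="10"/>
            <distal x="10" y="0" z="0" diameter="10"/>
        </segment>
        <segment id="1" name="dendrite">
            <parent segment="0" fractionAlong="1.0"/>
            <distal x="30" y="0" z="0" diameter="4"/>
        </segment>
        <segmentGroup id="all">
            <member segment="0"/>
            <member segment="1"/>
        </segmentGroup>
    </morphology>
</neuroml>
"""

# 3-record toy: soma root with two child nodes -> 2 segments sharing the
# root's proximal point.
SWC_TOY = """\
# toy reconstruction
1 1 0.0 0.0 0.0 5.0 -1
2 3 10.0 0.0 0.0 2.0 1
3 3 0.0 10.0 0.0 2.0 1
"""


def leaky_decay_model() -> LemsModel:
    return load_lems(LEMS_LEAKY_DECAY)


def izhikevich_model() -> LemsModel:
    return load_lems(LEMS_IZHIKEVICH)


def hindmarsh_rose_model() -> LemsModel:
    return load_lems(LEMS_HINDMARSH_ROSE)


def synapse_model() -> LemsModel:
    return load_lems(LEMS_SYNAPSE)


def two_segment_document():
    return loads_neuroml_xml(NEUROML_TWO_SEGMENT_XML)


def example_network_document(seed: int = 42):
    """The two-population random integrate-and-fire network (5 x 5, p = 0.3)."""
    return build_random_network(NetGenSpec(seed=seed))
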