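"""Dependency layering and deterministic feedback breaking.

Plain species are layer 0.  Each reaction or equation is assigned the
layer one deeper than its deepest dependency, so evaluating layers in
ascending order lets every node read current-step values of its upstream
nodes.  Feedback loops cannot be layered this way; the earliest-defined
unresolved node (model definition order) is picked to "break" the loop
and assigned layer N+1 where N is the deepest layer so far, its
unresolved dependencies are severed (the engine gives them a one-step
delay), and layering resumes -- repeating if further loops remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import ModelSpec


@dataclass(frozen=True)
class LayerAssignment:
    """Deterministic layering of a model's computed nodes.

    ``layer_of`` maps reaction/equation names to layers >= 1 (plain
    species are implicitly layer 0).  ``broken_edges`` lists
    (node, upstream) dependencies severed to break cycles; it is empty
    iff the dependency graph is acyclic.
    """

    layer_of: dict[str, int]
    broken_edges: tuple[tuple[str, str], ...]
    max_layer: int
    #: node names grouped by layer, authored order within a layer
    schedule: tuple[tuple[str, ...], ...] = field(default=())

    def broken_inputs_of(self, name: str) -> frozenset[str]:
        return frozenset(up for node, up in self.broken_edges if node == name)


def build_dependency_layers(m: ModelSpec) -> LayerAssignment:
    """Assign evaluation layers; pure function of the model (and its
    authored reaction order)."""
    order = m.node_order()
    index = {name: i for i, name in enumerate(order)}
    computed = set(order)
    # dependencies that are themselves computed nodes; plain species are
    # always resolved (layer 0)
    deps = {name: [d for d in m.dependencies_of(name) if d in computed]
            for name in order}

    layer_of: dict[str, int] = {}
    broken: list[tuple[str, str]] = []
    severed: dict[str, set[str]] = {name: set() for name in order}

    while len(layer_of) < len(order):
        progressed = True
        while progressed:
            progressed = False
            for name in order:
                if name in layer_of:
                    continue
                active = [d for d in deps[name] if d not in severed[name]]
                if all(d in layer_of for d in active):
                    layer_of[name] = 1 + max(
                        (layer_of[d] for d in active), default=0)
                    progressed = True
        if len(layer_of) == len(order):
            break
        # a cycle remains: break it at the earliest-defined unresolved node
        breaker = min((n for n in order if n not in layer_of),
                      key=index.__getitem__)
        deepest = max(layer_of.values(), default=0)
        for d in deps[breaker]:
            if d not in layer_of:  # includes a self-dependency
                severed[breaker].add(d)
                broken.append((breaker, d))
        layer_of[breaker] = deepest + 1

    max_layer = max(layer_of.values(), default=0)
    schedule = tuple(
        tuple(n for n in order if layer_of[n] == lvl)
        for lvl in range(1, max_layer + 1))
    return LayerAssignment(layer_of=layer_of, broken_edges=tuple(broken),
                           max_layer=max_layer, schedule=schedule)
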