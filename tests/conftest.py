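import json

import numpy as np
import pytest

import hilltau as ht


def build_model(doc: dict) -> ht.ModelSpec:
    """Author a model as a plain dict and load it through the JSON path."""
    return ht.load_model(json.dumps(doc))


@pytest.fixture
def binding_model():
    """Single activation reaction: output = mol * L / (KA + L), tau = 1 s."""
    return ht.example_model("binding")


@pytest.fixture
def feedback_model():
    return ht.example_model("feedback_inhibition")


@pytest.fixture
def bistable_model():
    return ht.example_model("bistable")


@pytest.fixture
def oscillator_model():
    return ht.example_model("oscillator")


@pytest.fixture
def bcm_model():
    return ht.example_model("bcm")


def random_reaction_params(rng: np.random.Generator) -> dict:
    """Random but valid Hill-reaction parameters for property tests."""
    return {
        "KA": float(rng.uniform(0.05, 5.0)),
        "n": float(rng.uniform(0.2, 4.0)),
        "tau": float(rng.uniform(0.1, 20.0)),
        "gain": float(rng.uniform(0.1, 10.0)),
    }


def brute_force_longest_path(deps: dict[str, list[str]], inputs: set[str],
                             node: str) -> int:
    """Independent oracle: longest dependency path from any layer-0 input.

    Exponential-time recursion; fine for graphs of <= 10 nodes.
    """
    best = 0
    for d in deps.get(node, []):
        if d in inputs:
            best = max(best, 1)
        else:
            best = max(best, 1 + brute_force_longest_path(deps, inputs, d))
    return best


def random_dag_model(rng: np.random.Generator, n_nodes: int) -> ht.ModelSpec:
    """Random acyclic model: each reaction depends on earlier names only."""
    doc = {"units": "uM", "species": {"in0": 1.0, "in1": 1.0},
           "reactions": {}}
    available = ["in0", "in1"]
    for i in range(n_nodes):
        k = int(rng.integers(1, min(3, len(available)) + 1))
        deps = list(rng.choice(available, size=k, replace=False))
        r = {"input": deps[0], "KA": 1.0, "tau": 1.0}
        if len(deps) > 1:
            r["ligand"] = deps[1]
        if len(deps) > 2:
            r["modifier"] = deps[2]
            r["Kmod"] = 1.0
        name = f"r{i}"
        doc["reactions"][name] = r
        available.append(name)
    return build_model(doc)


def random_cyclic_model(rng: np.random.Generator, n_nodes: int) -> ht.ModelSpec:
    """Random model where dependencies may point anywhere (cycles likely)."""
    names = [f"r{i}" for i in range(n_nodes)]
    doc = {"units": "uM", "species": {"in0": 1.0}, "reactions": {}}
    pool = ["in0"] + names
    for name in names:
        k = int(rng.integers(1, 3))
        deps = list(rng.choice(pool, size=k, replace=False))
        r = {"input": deps[0], "KA": 1.0, "tau": 1.0}
        if len(deps) > 1 and deps[1] != deps[0]:
            r["ligand"] = deps[1]
        doc["reactions"][name] = r
    return build_model(doc)
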