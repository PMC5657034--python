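import json
import random

import pytest

from dcjrna import fixtures as fx


@pytest.fixture(scope="session")
def trna_pair():
    """The bundled E. coli tRNA-Leu / tRNA-Ala example pair."""
    return fx.load_structure("trna_leu"), fx.load_structure("trna_ala")


@pytest.fixture(scope="session")
def expected_assignments():
    text = (
        __import__("importlib.resources", fromlist=["files"])
        .files("dcjrna")
        .joinpath("data/expected_assignments.json")
        .read_text()
    )
    return json.loads(text)


@pytest.fixture()
def rng():
    return random.Random(20240917)


def random_pair(seed: int):
    """A structure and a perturbed relative, for pipeline round trips."""
    r = random.Random(seed)
    n = r.randint(3, 7)
    s = fx.random_structure(
        fx.GeneratorConfig(n_components=n, length=30 * n, seed=seed)
    )
    t = s
    for _ in range(r.randint(1, 3)):
        op = r.choice(["delete", "insert", "swap", "resize"])
        try:
            if op == "delete" and len(t) > 1:
                t = fx.delete_components(t, 1, r)
            elif op == "insert":
                t = fx.insert_component(t, r)
            elif op == "swap":
                t = fx.swap_adjacent_blocks(t, r)
            else:
                t = fx.resize_stem(t, r)
        except Exception:
            continue  # some perturbations are infeasible on some shapes
    return s, t.with_name(f"{s.name}_p")
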