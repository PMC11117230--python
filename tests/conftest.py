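import numpy as np
import pandas as pd
import pytest

import biphasic as bp


@pytest.fixture
def toy_tree() -> bp.Phylogeny:
    """((A:1,B:1):1,C:2); — the 3-tip workhorse."""
    return bp.Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced4() -> bp.Phylogeny:
    return bp.Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def template() -> np.ndarray:
    return bp.default_template()


@pytest.fixture
def small_study() -> bp.SyntheticStudy:
    """A down-sized synthetic study for pipeline plumbing tests."""
    return bp.make_study(
        seed=11,
        family_sizes={
            "Alsodidae": 6,
            "Batrachylidae": 4,
            "Cycloramphidae": 5,
            "Hylodidae": 7,
        },
        n_alt_trees=3,
    )


def random_similarity(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply a random rotation/scale/translation to a configuration."""
    th = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return rng.uniform(0.5, 2.0) * (coords @ rot.T) + rng.uniform(-5, 5, 2)


def pectinate_newick(n: int, step: float = 1.0) -> str:
    """Fully imbalanced (caterpillar) ultrametric newick with n tips."""
    tip_depth = (n - 1) * step
    inner = f"(t1:{step},t2:{step})"
    depth = step
    for i in range(3, n + 1):
        inner = f"({inner}:{step},t{i}:{depth + step})"
        depth += step
    assert abs(depth - tip_depth) < 1e-9
    return inner + ";"
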