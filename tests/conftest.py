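"""Shared fixtures: reference knowledge bases, dimension trees, and random
instance generation with an independent exact-rational oracle."""

from __future__ import annotations

import random
from fractions import Fraction
from types import SimpleNamespace

import pytest

from diaet import (
    DimensionTree,
    EndpointSpec,
    EventSpec,
    KBSpec,
    glaucoma_spec,
    load_kb,
    parse_dimension_config,
    t2dm_spec,
    write_kb,
)
from diaet.dimensions import DimensionNode, LeafBinding


def load_example_config(name: str) -> DimensionTree:
    from importlib import resources

    text = (resources.files("diaet") / f"resources/configs/{name}.yaml").read_text()
    return parse_dimension_config(text)


@pytest.fixture(scope="session")
def glaucoma(tmp_path_factory):
    """The 11-trial latanoprost-vs-timolol case: KB on disk, loaded handle,
    and its dimension tree."""
    spec = glaucoma_spec()
    path = tmp_path_factory.mktemp("kb") / "glaucoma.ttl"
    write_kb(spec, path)
    return SimpleNamespace(
        spec=spec, path=path, kb=load_kb(path), tree=load_example_config("glaucoma")
    )


@pytest.fixture(scope="session")
def t2dm(tmp_path_factory):
    """The 9-trial insulin glargine vs NPH case (4/9 efficacy, 9/9 safety)."""
    spec = t2dm_spec()
    path = tmp_path_factory.mktemp("kb") / "t2dm.ttl"
    write_kb(spec, path)
    return SimpleNamespace(
        spec=spec, path=path, kb=load_kb(path), tree=load_example_config("t2dm")
    )


# ---------------------------------------------------------------------------
# Random instances + oracle
# ---------------------------------------------------------------------------


def random_instance(seed: int) -> tuple[KBSpec, DimensionTree]:
    """A small random KB spec plus a matching random dimension tree.

    All weights are strictly positive so aggregation is never degenerate;
    evidence counts may be zero (exercising the no-evidence paths).
    """
    rng = random.Random(seed)
    endpoints = [
        EndpointSpec(
            endpoint_id=f"endpoint_{i}",
            direction=rng.choice(["decrease", "increase"]),
            n_supporting=rng.randint(0, 5),
            n_contradicting=rng.randint(0, 4),
            n_nonreporting=rng.randint(0, 2),
            n_ties=rng.randint(0, 1),
            unit="units",
        )
        for i in range(rng.randint(1, 2))
    ]
    events = [
        EventSpec(
            event_id=f"event_{i}",
            n_supporting=rng.randint(0, 5),
            n_contradicting=rng.randint(0, 4),
            n_nonreporting=rng.randint(0, 2),
            n_ties=rng.randint(0, 1),
        )
        for i in range(rng.randint(0, 2))
    ]
    spec = KBSpec(
        drug1="drugA",
        drug2="drugB",
        endpoints=tuple(endpoints),
        events=tuple(events),
        n_trials=None,
        participants_range=(20, 200),
        seed=rng.randrange(2**31),
    )

    leaves = [
        DimensionNode(
            id=f"leaf_{e.endpoint_id}",
            label=e.endpoint_id,
            weight=Fraction(rng.randint(1, 4), rng.choice([1, 2])),
            binding=LeafBinding("efficacy", e.endpoint_id, e.direction),
        )
        for e in endpoints
    ] + [
        DimensionNode(
            id=f"leaf_{e.event_id}",
            label=e.event_id,
            weight=Fraction(rng.randint(1, 4), rng.choice([1, 2])),
            binding=LeafBinding("safety", e.event_id),
        )
        for e in events
    ]
    rng.shuffle(leaves)
    # group some leaves under intermediate dimensions, keep the rest direct
    children: list[DimensionNode] = []
    i = 0
    while i < len(leaves):
        take = rng.randint(1, len(leaves) - i)
        group = leaves[i:i + take]
        if len(group) == 1 and rng.random() < 0.5:
            children.extend(group)
        else:
            children.append(
                DimensionNode(
                    id=f"group_{i}",
                    label=f"group {i}",
                    weight=Fraction(rng.randint(1, 4), rng.choice([1, 2])),
                    children=tuple(group),
                )
            )
        i += take
    root = DimensionNode(id="root", label="Overall", weight=Fraction(1),
                         children=tuple(children))
    return spec, DimensionTree(root)


def leaf_confidences(spec: KBSpec) -> dict[str, Fraction | None]:
    """Expected leaf confidence per target id, straight from the spec counts
    (ties contradict): supporting / reporting, or None without evidence."""
    out: dict[str, Fraction | None] = {}
    for dim in (*spec.endpoints, *spec.events):
        target = dim.endpoint_id if isinstance(dim, EndpointSpec) else dim.event_id
        out[target] = (
            Fraction(dim.n_supporting, dim.n_reporting) if dim.n_reporting else None
        )
    return out


def oracle_confidences(
    tree: DimensionTree, leaf_conf: dict[str, Fraction | None]
) -> dict[str, Fraction | None]:
    """Naive bottom-up exact-rational weighted mean over the dimension tree,
    independent of the package's construction path. None = no evidence."""
    out: dict[str, Fraction | None] = {}

    def walk(node: DimensionNode) -> Fraction | None:
        if node.is_leaf:
            value = leaf_conf.get(node.binding.target_id)
        else:
            parts = [(c.weight, walk(c)) for c in node.children]
            evidenced = [(w, v) for w, v in parts if v is not None]
            if not evidenced:
                value = None
            else:
                value = sum(w * v for w, v in evidenced) / sum(w for w, _ in evidenced)
        out[node.id] = value
        return value

    walk(tree.root)
    return out
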