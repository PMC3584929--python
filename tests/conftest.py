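"""Shared fixtures: tiny synthetic worlds and on-disk toy inputs."""

from __future__ import annotations

import pytest

from clannot import generate_world


TOY_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root

[Term]
id: GO:0000010
name: branch one
is_a: GO:0000001 ! root

[Term]
id: GO:0000011
name: branch two
is_a: GO:0000001 ! root

[Term]
id: GO:0000100
name: leaf under one
is_a: GO:0000010 ! branch one

[Term]
id: GO:0000101
name: leaf under both
is_a: GO:0000010 ! branch one
is_a: GO:0000011 ! branch two

[Term]
id: GO:0000200
name: deep leaf
is_a: GO:0000100 ! leaf under one
"""


@pytest.fixture()
def toy_obo(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return path


@pytest.fixture(scope="session")
def small_world():
    """5 families of 5 members over 60 decoys; fast enough for most tests."""
    return generate_world(
        n_families=5, members_per_family=5, n_decoys=60,
        background_terms=10, background_rate=0.05, seed=7,
    )


def write_hits(world, path):
    path.write_text("\n".join(world.alignment_rows) + "\n")
    return path
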