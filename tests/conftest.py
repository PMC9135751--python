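"""Shared fixtures: small phantoms and meshes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from fetalfold import (
    LabelVolume,
    PhantomSpec,
    assign_regions,
    extract_junction_mesh,
    make_phantom,
)


@pytest.fixture(scope="session")
def sphere_spec() -> PhantomSpec:
    """Unfolded phantom: 20 mm white-matter sphere, 1 mm isotropic, no accessories."""
    return PhantomSpec.create(
        wm_radius=20.0, fold_amplitude=0.0, spacing=(1, 1, 1), with_accessories=False
    )


@pytest.fixture(scope="session")
def sphere_phantom(sphere_spec):
    return make_phantom(sphere_spec, seed=0)


@pytest.fixture(scope="session")
def sphere_mesh(sphere_phantom):
    seg, parc = sphere_phantom
    mesh = extract_junction_mesh(seg, ("wm",))
    assign_regions(mesh, parc)
    return mesh


def cuboid_label_volume(
    size_mm: tuple[float, float, float] = (20.0, 20.0, 20.0),
    spacing: float = 1.0,
    pad_mm: float = 4.0,
) -> LabelVolume:
    """Solid cuboid of white-matter label centred in an empty grid."""
    half = np.asarray(size_mm) / 2.0
    n = np.ceil((np.asarray(size_mm) + 2 * pad_mm) / spacing).astype(int) + 1
    center = (n - 1) / 2.0 * spacing
    data = np.zeros(tuple(n), dtype=np.int16)
    ax = [np.arange(n[i]) * spacing - center[i] for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    inside = (
        (np.abs(X) <= half[0]) & (np.abs(Y) <= half[1]) & (np.abs(Z) <= half[2])
    )
    data[inside] = 2  # wm
    return LabelVolume(data, (spacing,) * 3)
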