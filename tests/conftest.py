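"""Shared fixtures: phantoms are built once per session and reused."""

import numpy as np
import pytest
import trimesh

from toothprep import (
    EvalConfig,
    PhantomSpec,
    evaluate_specimen,
    make_phantom_pair,
    phantom_eval_config,
)


@pytest.fixture(scope="session")
def default_phantom():
    """Default abutment phantom: 12° TOC in both planes, 1.5 mm reductions,
    0.4 mm chamfer, 10 µm scan noise."""
    spec = PhantomSpec()
    anatomical, prepared, truth, pts = make_phantom_pair(spec)
    return spec, anatomical, prepared, truth, pts


@pytest.fixture(scope="session")
def default_result(default_phantom):
    spec, anatomical, prepared, truth, pts = default_phantom
    return evaluate_specimen(anatomical, prepared, pts, phantom_eval_config(spec))


@pytest.fixture(scope="session")
def blob():
    """Asymmetric closed test mesh (anisotropic sphere with a bump):
    rotationally unambiguous, good for registration and closest-point tests."""
    m = trimesh.creation.icosphere(3)
    v = np.asarray(m.vertices) * [1.0, 0.7, 0.5]
    v[:, 2] += 0.3 * np.exp(-((v[:, 0] - 0.5) ** 2 + v[:, 1] ** 2) / 0.1)
    return trimesh.Trimesh(v, m.faces.copy(), process=False)


def rotation_matrix(axis, angle_rad):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * k @ k
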