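import numpy as np
import pytest

from ccmorph import (
    CohortConfig,
    RadiusProfile,
    make_medial_curve,
    make_tube_surface,
    make_template,
    parameterize_mesh,
    sample_subject,
    feature_field,
    derive_seed,
)


def cylinder_mesh(radius=5.0, length=100.0, dims=(16, 8)):
    """A straight circular cylinder along x with two open ends."""
    curve = make_medial_curve(64, 0.0, length)
    n_th = 8
    prof = RadiusProfile(
        np.linspace(0, 1, 8),
        np.arange(n_th) * 2 * np.pi / n_th,
        np.full((8, n_th), radius),
    )
    return make_tube_surface(curve, prof, dims)


@pytest.fixture(scope="session")
def straight_cylinder():
    return cylinder_mesh()


@pytest.fixture(scope="session")
def arched_mesh():
    """A noise-free callosum-like tube (the deterministic group template)."""
    cfg = CohortConfig(noise_sd=0.0, scale_jitter_sd=0.0, rigid_rot_deg=0.0,
                       rigid_trans_mm=0.0)
    return sample_subject(cfg, "A", 1)


def cohort_fields(cfg, feature_kwargs=None):
    """Parameterize a whole synthetic cohort and return per-group features.

    Returns (fields_a, fields_b, template); the template is the rigidly
    aligned vertex-wise mean of group A.
    """
    grids = {"A": [], "B": []}
    for group in ("A", "B"):
        for k in range(cfg.n_per_group):
            sid = f"{group}{k:03d}"
            mesh = sample_subject(cfg, group, derive_seed(cfg.seed, "subject", sid))
            grids[group].append(parameterize_mesh(mesh, cfg.grid_dims))
    template = make_template(grids["A"])
    kw = feature_kwargs or {}
    fields_a = [feature_field(g, template, **kw) for g in grids["A"]]
    fields_b = [feature_field(g, template, **kw) for g in grids["B"]]
    return fields_a, fields_b, template
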