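import dataclasses

import pytest

import octneck as on


@pytest.fixture(scope="session")
def default_phantom():
    """One mid-sized phantom with a 0.55 mm^2 designed gap, shared read-only."""
    base = on.PhantomConfig(seed=11)
    cfg = dataclasses.replace(base, designed_gap=on.gap_spec_for_area(base, 0.55))
    volume, truth, annotation = on.generate_phantom(cfg)
    return cfg, volume, truth, annotation


@pytest.fixture(scope="session")
def classified_phantom(default_phantom):
    cfg, volume, truth, annotation = default_phantom
    labels = on.classify_volume(volume, n_radii=cfg.n_radii)
    neck = on.build_neck_surface(annotation, volume.geometry)
    cmap = on.build_coverage_map(labels, neck)
    return cfg, volume, truth, annotation, labels, neck, cmap


@pytest.fixture(scope="session")
def noise_free_wall_phantom():
    """Bare tissue wall, no struts, no speckle: closed-form geometry."""
    cfg = dataclasses.replace(on.PhantomConfig(seed=0), speckle_contrast=0.0, strut_pattern=())
    volume, truth, annotation = on.generate_phantom(cfg)
    return cfg, volume, truth, annotation


@pytest.fixture()
def reference_cases():
    return on.load_reference_cases()
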