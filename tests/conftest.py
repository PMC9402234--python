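from __future__ import annotations

import pytest

from acmgsf import cohort_io
from acmgsf.panel import default_panel
from acmgsf.simulate import demo_config, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """The default end-to-end demo bundle (fixed seed, deterministic)."""
    out = tmp_path_factory.mktemp("demo")
    bundle, truth = simulate_cohort(demo_config(seed=0), out)
    return bundle, truth


@pytest.fixture(scope="session")
def demo_objects(demo_bundle):
    """Demo bundle loaded back through the ingest layer."""
    bundle, truth = demo_bundle
    matrix, stubs, samples = cohort_io.read_cohort(bundle.vcf, bundle.samples)
    variants = cohort_io.attach_annotations(stubs, bundle.annotations)
    sample_ids = {s.id for s in samples}
    kinship = cohort_io.read_kinship(bundle.kinship, known_samples=sample_ids)
    phenotypes = cohort_io.read_phenotypes(bundle.phenotypes, known_samples=sample_ids)
    return {
        "bundle": bundle,
        "truth": truth,
        "matrix": matrix,
        "variants": variants,
        "samples": samples,
        "kinship": kinship,
        "phenotypes": phenotypes,
    }
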