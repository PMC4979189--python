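import pytest

from targetec.design import (
    build_target_regions,
    cds_utr_sets,
    classify_regions,
    exon_union,
)
from targetec.fixtures import FixtureSpec, make_annotation_fixture


@pytest.fixture(scope="session")
def seed1_bundle():
    """Seed-1 synthetic annotation plus the design built from it."""
    spec = FixtureSpec(seed=1)
    space, models, track = make_annotation_fixture(spec)
    exons = exon_union(models, space)
    conserved = track.extract_conserved(1.0)
    targets = build_target_regions(exons, conserved, 100, space)
    cds, utr = cds_utr_sets(models)
    classes = classify_regions(targets, cds, utr, conserved)
    return {
        "spec": spec,
        "space": space,
        "models": models,
        "track": track,
        "exons": exons,
        "conserved": conserved,
        "targets": targets,
        "cds": cds,
        "utr": utr,
        "classes": classes,
    }
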