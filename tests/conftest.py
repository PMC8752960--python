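"""Shared fixtures: one mid-resolution HF heart with coordinates, and a
small two-subject, two-vein campaign reused across the metric, optimization
and statistics tests (session-scoped to amortize the simulation cost)."""

from dataclasses import replace

import numpy as np
import pytest

from crtlead.anatomy import (
    HF_SHAPE_MEAN,
    RR_SHAPE_MEAN,
    assign_rule_based_fibres,
    box_tet_mesh,
    generate_biventricular_mesh,
)
from crtlead.campaign import Subject, run_campaign
from crtlead.coordinates import compute_uvc, map_aha17
from crtlead.eikonal import ConductionParameters
from crtlead.leads import VEINS, locate_vein_line, place_electrodes, place_rv_electrode

CAMPAIGN_VEINS = ("LA", "AN")
CAMPAIGN_EDGE = 5.5


@pytest.fixture(scope="session")
def hf_mesh():
    mesh = generate_biventricular_mesh(HF_SHAPE_MEAN)
    coords = compute_uvc(mesh)
    return assign_rule_based_fibres(mesh, coords), coords


@pytest.fixture(scope="session")
def hf_aha(hf_mesh):
    _, coords = hf_mesh
    return map_aha17(coords)


def make_subject(subject_id, cohort, params, veins=CAMPAIGN_VEINS, seed=0):
    mesh = generate_biventricular_mesh(params, seed=seed)
    coords = compute_uvc(mesh)
    mesh = assign_rule_based_fibres(mesh, coords)
    aha = map_aha17(coords)
    leads = {
        v: place_electrodes(mesh, locate_vein_line(mesh, coords, aha, VEINS[v]))
        for v in veins
    }
    return Subject(
        subject_id=subject_id,
        cohort=cohort,
        mesh=mesh,
        coords=coords,
        leads=leads,
        rv_node=place_rv_electrode(mesh, coords, "APEX"),
    )


@pytest.fixture(scope="session")
def tiny_subjects():
    hf = replace(HF_SHAPE_MEAN, target_edge_length=CAMPAIGN_EDGE)
    rr = replace(RR_SHAPE_MEAN, target_edge_length=CAMPAIGN_EDGE)
    return [
        make_subject("HF01", "HF", hf),
        make_subject("RR01", "RR", rr),
    ]


@pytest.fixture(scope="session")
def tiny_campaign(tiny_subjects):
    return run_campaign(tiny_subjects, ConductionParameters(), veins=CAMPAIGN_VEINS)


@pytest.fixture(scope="session")
def unit_cube():
    return box_tet_mesh((10.0, 10.0, 10.0), edge=1.0)
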