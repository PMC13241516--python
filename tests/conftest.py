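"""Shared fixtures: synthetic scenes generated once per session."""

import numpy as np
import pytest

import ceodquant as cq


@pytest.fixture(scope="session")
def default_scene():
    """One default stressed scene: channels plus ground truth."""
    config = cq.SceneConfig(rng_seed=7)
    channels, droplets, condensates = cq.generate_scene(config)
    return {
        "config": config,
        "channels": channels,
        "droplets": droplets,
        "condensates": condensates,
    }


@pytest.fixture(scope="session")
def segmented_scene(default_scene):
    """The default scene run through segmentation, assignment and measurement."""
    params = cq.SegmentationParams()
    droplet_labels = cq.segment_droplets(default_scene["channels"].reporter, params)
    condensate_labels = cq.segment_condensates(default_scene["channels"].marker, params)
    parents = cq.assign_condensates(droplet_labels, condensate_labels)
    droplet_records = cq.measure_objects(droplet_labels, default_scene["channels"].reporter)
    condensate_records = cq.measure_objects(
        condensate_labels, default_scene["channels"].marker, parents
    )
    return {
        **default_scene,
        "params": params,
        "droplet_labels": droplet_labels,
        "condensate_labels": condensate_labels,
        "parents": parents,
        "droplet_records": droplet_records,
        "condensate_records": condensate_records,
    }


@pytest.fixture(scope="session")
def multi_scene_cohort():
    """Nine full scenes (~225 droplets) for end-to-end recovery statistics."""
    scenes = []
    for i in range(9):
        config = cq.SceneConfig(rng_seed=100 + i)
        channels, droplets, condensates = cq.generate_scene(config)
        scenes.append((config, channels, droplets, condensates))
    return scenes


def match_droplets_to_truth(droplet_records, droplets_gt):
    """Map each detected droplet record to the nearest ground-truth droplet."""
    out = {}
    for rec in droplet_records:
        best = min(
            droplets_gt,
            key=lambda d: (d.center_x_um - rec.centroid_x_um) ** 2
            + (d.center_y_um - rec.centroid_y_um) ** 2,
        )
        out[rec.label] = best
    return out
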