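"""Shared fixtures: the packaged panel and reusable synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from rtmis import classifier as clf
from rtmis import simdata
from rtmis.panel import PanelDefinition, default_panel, load_panel
from rtmis.readproc import ReadLayout


@pytest.fixture(scope="session")
def panel() -> PanelDefinition:
    return default_panel()


@pytest.fixture(scope="session")
def layout(panel) -> ReadLayout:
    return ReadLayout(umi_length=panel.umi_length,
                      insert_offset=panel.umi_length)


def make_small_panel(tmp_path, rows):
    """Write a throwaway panel TSV and load it."""
    path = tmp_path / "panel.tsv"
    lines = ["marker_id\tgene\tgroup\tpair_index\tleft_seq\tright_seq"]
    for r in rows:
        lines.append("\t".join(map(str, r)))
    path.write_text("\n".join(lines) + "\n")
    return load_panel(path)


@pytest.fixture()
def small_panel(tmp_path) -> PanelDefinition:
    """Three well-separated expression probes plus one mutation locus."""
    return make_small_panel(tmp_path, [
        ("MME_1", "MME", "GCB_SIG", 1, "ACGTACGTACGTACGTACGT", "TTTTGGGGCCCCAAAATTTT"),
        ("CD5_1", "CD5", "B_CELL", 1, "GGGGCCCCAAAATTTTGGGG", "ACACACACGTGTGTGTACAC"),
        ("MYC_1", "MYC", "DOUBLE_EXPRESSOR", 1, "TGCATGCATGCATGCATGCA", "CCGGAATTCCGGAATTCCGG"),
        ("MYC_2", "MYC", "DOUBLE_EXPRESSOR", 2, "AATTGGCCAATTGGCCAATT", "GTGTACACGTGTACACGTGT"),
        ("MYD88_L265P_1", "MYD88_L265P", "MUTATION", 1,
         "CACGTAGCTCACGTAGCTCA", "GAGCTATGGAGCTATGGAGC"),
        ("MYD88_L265P_2", "MYD88_L265P", "MUTATION", 2,
         "TCCATGGACTCCATGGACTC", "AGGTCAGTAAGGTCAGTAAG"),
    ])


@pytest.fixture(scope="session")
def default_cohort():
    """Reference synthetic cohort: 7 classes x 40 samples, default noise."""
    return simdata.simulate_cohort(simdata.SimConfig(n_per_class=40, seed=1))


@pytest.fixture(scope="session")
def split_labeled_cohort(default_cohort, panel):
    cohort = default_cohort.to_labeled_cohort(panel)
    return clf.split_cohort(cohort, seed=1)


@pytest.fixture(scope="session")
def trained_model(split_labeled_cohort):
    """Forest at reduced tree count for test runtime; seeds fixed."""
    return clf.train(split_labeled_cohort,
                     clf.ForestConfig(n_trees=500, seed=1))
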