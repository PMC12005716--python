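import pytest

from karyolg.pipeline import RunConfig, run_pipeline
from karyolg.scenarios import Scenario, chiton_scenario


@pytest.fixture(scope="session")
def chiton_run(tmp_path_factory):
    """One full pipeline run on the bundled chiton scenario (seed 1)."""
    outdir = tmp_path_factory.mktemp("chiton_run")
    config = RunConfig(outdir=str(outdir), seed=1, scenario="builtin:chiton")
    return run_pipeline(config)


@pytest.fixture(scope="session")
def small_scenario():
    """The chiton scenario scaled to 30 genes per linkage group for speed."""
    sc = chiton_scenario()
    return Scenario(
        name="chiton_small",
        n_lgs=sc.n_lgs,
        genes_per_lg=30,
        tree_newick=sc.tree_newick,
        rates=sc.rates,
        translocation_k=sc.translocation_k,
        events=sc.events,
    )


def truth_mapping(linkage_groups, mlg_map):
    """Map each inferred linkage group to its majority true linkage group."""
    from collections import Counter

    mapping = {}
    for lg in linkage_groups:
        counts = Counter(mlg_map[og] for og in lg.member_og_ids)
        mapping[lg.mlg_id] = counts.most_common(1)[0][0]
    return mapping
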