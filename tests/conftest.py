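import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_scene():
    """A 12-gene scene shared by tests that only need a consistent fixture."""
    from pitkit import SimParams, simulate_scene

    return simulate_scene(SimParams(seed=7, n_genes=12, n_psms=800))


@pytest.fixture(scope="session")
def scene_pipeline(small_scene):
    """Scene run through ORF finding, decoys, PSM simulation, FDR and grouping."""
    import pitkit as pk

    scene = small_scene
    records, index = pk.build_orf_database(scene.transcripts)
    db = pk.generate_decoy_database(records)
    params = pk.SimParams(seed=7, n_genes=12, n_psms=800)
    true_seqs = [info["aa"] for info in scene.truth.orfs.values()]
    psms, labels = pk.simulate_psms(db, params, true_proteins=true_seqs)
    peptides = pk.compute_q_values(pk.peptide_level_scores(psms))
    retained = pk.filter_peptides(peptides, 0.01)
    evidence, unmapped = pk.map_peptides_to_proteins(retained, db)
    pags = pk.group_proteins(evidence, 2)
    return {
        "scene": scene,
        "records": records,
        "index": index,
        "db": db,
        "psms": psms,
        "labels": labels,
        "peptides": peptides,
        "retained": retained,
        "evidence": evidence,
        "unmapped": unmapped,
        "pags": pags,
    }
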