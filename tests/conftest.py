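import pytest

from defensomics import homology, synthetic


@pytest.fixture(scope="session")
def refdb():
    return synthetic.generate_reference_db(n_per_role=2, mean_len=150, seed=5)


@pytest.fixture(scope="session")
def refdb_single():
    return synthetic.generate_reference_db(n_per_role=1, mean_len=100, seed=1)


@pytest.fixture(scope="session")
def aligner():
    return homology.make_aligner()


@pytest.fixture(scope="session")
def small_rm_cohort(refdb):
    """30 clean genomes (completeness 1, identity 0.75) with ground truth."""
    return synthetic.generate_rm_cohort(30, refdb, seed=11, identity=0.75)


def detect_cohort(genomes, refdb, calls, aligner, **kwargs):
    """Run the homology + RM stages over a cohort; returns calls per genome."""
    from defensomics import rm_detection

    out = {}
    for gid, genome in genomes.items():
        hits = homology.search_genome(genome, refdb, aligner=aligner)
        assignments = homology.best_hit_assign(hits, refdb, **kwargs)
        ext = calls[calls["genome_id"] == gid] if calls is not None else None
        out[gid] = rm_detection.call_rm_systems(genome, assignments, ext)
    return out


def score_against_plan(detected, plan):
    """Type-level precision/recall of detected RM calls vs the plan."""
    tp = fp = fn = 0
    per_type = {}
    for gid, calls in detected.items():
        got = {(c.rm_type, c.anchor_gene_id) for c in calls}
        want = set(plan.expected_rm_calls(gid))
        tp += len(got & want)
        fp += len(got - want)
        fn += len(want - got)
        for t, anchor in want:
            rec = per_type.setdefault(t, [0, 0])
            rec[1] += 1
            if (t, anchor) in got:
                rec[0] += 1
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    recall_by_type = {t: hits / total for t, (hits, total) in per_type.items() if total}
    return precision, recall, recall_by_type
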