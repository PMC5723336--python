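import numpy as np
import pytest

from placeprof.formats import SeqRecord, parse_newick_numbered
from placeprof.refpkg import ModelSpec, build_refpkg


@pytest.fixture(scope="session")
def four_taxon_refpkg():
    """A 4-leaf reference package with distinct 40-residue rows."""
    rng = np.random.default_rng(1234)
    from placeprof.matrices import AA_ORDER

    base = "".join(rng.choice(list(AA_ORDER), 40))

    def mutate(seq, n, seed):
        r = np.random.default_rng(seed)
        s = list(seq)
        for pos in r.choice(len(s), size=n, replace=False):
            s[pos] = AA_ORDER[int(r.integers(20))]
        return "".join(s)

    aln = [
        SeqRecord("A", base),
        SeqRecord("B", mutate(base, 6, 1)),
        SeqRecord("C", mutate(base, 12, 2)),
        SeqRecord("D", mutate(base, 14, 3)),
    ]
    tree = parse_newick_numbered("((A:0.12,B:0.3):0.07,(C:0.25,D:0.2):0.1);")
    return build_refpkg(
        "toy", aln, tree, {"AB": {"A", "B"}}, {"D"}, ModelSpec(alpha=0.8, k=2)
    )


@pytest.fixture(scope="session")
def basic_scenario():
    from placeprof.synth import make_benchmark_scenario

    return make_benchmark_scenario("basic", seed=11, n_pairs=400)


@pytest.fixture(scope="session")
def basic_run(basic_scenario, tmp_path_factory):
    """The basic scenario materialized and run end-to-end once."""
    from placeprof.pipeline import RunConfig, SampleInput, run_pipeline
    from placeprof.synth import write_scenario

    root = tmp_path_factory.mktemp("basic_run")
    data = write_scenario(basic_scenario, root / "data")
    meta, _spec = basic_scenario.samples[0]
    config = RunConfig(
        refpkg_paths={
            g: str(data / "refpkgs" / g) for g in basic_scenario.refpkgs
        },
        samples=[
            SampleInput(
                meta.sample_id,
                str(data / f"{meta.sample_id}_R1.fastq"),
                str(data / f"{meta.sample_id}_R2.fastq"),
                station=meta.station,
                depth=meta.depth,
                fraction=meta.fraction,
            )
        ],
        out_dir=str(root / "out"),
    )
    out = run_pipeline(config)
    return basic_scenario, data, out
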