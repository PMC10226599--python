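import numpy as np
import pytest

from cleavecall.annotation_io import GenomeSequence, TranscriptModel
from cleavecall.degradome_quant import NormalizedProfile, cpm_normalize, merge_replicates
from cleavecall.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture
def two_exon_plus():
    return TranscriptModel(
        transcript_id="t1",
        gene_id="g1",
        chromosome="chr1",
        strand="+",
        exons=[(0, 100), (200, 300)],
        cds_span=(50, 250),
        is_protein_coding=True,
    )


@pytest.fixture
def two_exon_minus():
    return TranscriptModel(
        transcript_id="t2",
        gene_id="g2",
        chromosome="chr1",
        strand="-",
        exons=[(0, 100), (200, 300)],
        cds_span=(50, 250),
        is_protein_coding=True,
    )


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    return GenomeSequence(
        name="toy",
        chromosomes={"chr1": "".join(bases[rng.integers(0, 4, 1000)])},
    )


def _merge(ds, genotype):
    reps = sorted(r for (g, r) in ds.profiles if g == genotype)
    return merge_replicates([cpm_normalize(ds.profiles[(genotype, r)]) for r in reps])


# Smaller transcriptome => proportionally fatter background, so the planted
# effects are stronger than the full-scale defaults to keep margins wide.
SMALL_SIM_CONFIG = dict(
    seed=7,
    n_transcripts=40,
    depth=2_000_000,
    utr5_range=(80, 150),
    cds_range=(400, 800),
    utr3_range=(100, 200),
    cleavage_effect_log2=4.0,
    cleavage_spike_cpm=80.0,
    background_fraction=0.05,
    decap_sigma=0.3,
)


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated dataset shared across tests (read-only)."""
    ds = simulate_dataset(SimulationConfig(**SMALL_SIM_CONFIG))
    merged = {g: _merge(ds, g) for g in ("wild_type", "xrn4", "dne1_xrn4")}
    cap = cpm_normalize(ds.cap_pare)
    return ds, merged, cap


@pytest.fixture(scope="session")
def small_sim_result(small_sim):
    from cleavecall.site_caller import run_cascade

    ds, merged, cap = small_sim
    result = run_cascade(
        merged["xrn4"],
        merged["wild_type"],
        merged["dne1_xrn4"],
        cap,
        ds.genome,
        ds.truth.transcripts,
        rnaseq_table=ds.rnaseq,
    )
    return ds, result


def make_profile(values, genotype="xrn4", library_id=None, chrom="chr1", strand="+"):
    """NormalizedProfile from {pos: cpm} or {(chrom, strand, pos): cpm}."""
    out = {}
    for k, v in values.items():
        key = k if isinstance(k, tuple) else (chrom, strand, k)
        out[key] = float(v)
    return NormalizedProfile(
        library_id=library_id or f"{genotype}_test",
        genotype=genotype,
        replicate=1,
        values=out,
    )
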