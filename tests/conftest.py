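import pytest

from polmutscan.models import GeneModel, GenomeSequence, Transcript, Variant
from polmutscan.simulate import SimulationConfig, simulate


def _toy_sequence() -> str:
    """300 bp with a + strand mini-gene (CDS 'ATGGCTTAA' at [100,109)) and a
    - strand mini-gene (CDS reads 'ATGGCTTAA', genomic 'TTAAGCCAT' at [200,209))."""
    base = list(("ACGT" * 75)[:300])
    base[100:109] = "ATGGCTTAA"
    base[200:209] = "TTAAGCCAT"
    return "".join(base)


@pytest.fixture(scope="session")
def toy_genome() -> GenomeSequence:
    return GenomeSequence({"chr1": _toy_sequence()})


@pytest.fixture(scope="session")
def toy_genes() -> list[GeneModel]:
    plus = GeneModel(
        gene_id="gplus",
        chrom="chr1",
        strand="+",
        start=80,
        end=130,
        transcripts=[
            Transcript(
                transcript_id="gplus.t1",
                exons=[(80, 130)],
                cds=[(100, 109)],
                utr5=[(80, 100)],
                utr3=[(109, 130)],
            )
        ],
    )
    minus = GeneModel(
        gene_id="gminus",
        chrom="chr1",
        strand="-",
        start=180,
        end=240,
        transcripts=[
            Transcript(
                transcript_id="gminus.t1",
                exons=[(180, 240)],
                cds=[(200, 209)],
                utr5=[(209, 240)],
                utr3=[(180, 200)],
            )
        ],
    )
    return [plus, minus]


def snp(pos: int, ref: str, alt: str, chrom="chr1", qual=50.0, depth=40) -> Variant:
    """1-based SNP shorthand for tests."""
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual, depth=depth)


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated dataset shared by read-only tests."""
    cfg = SimulationConfig(
        seed=11,
        n_chrom=2,
        chrom_length=400_000,
        n_genes=30,
        n_deg_up=4,
        n_deg_down=5,
        n_effect_plants=20,
        effect_mix={
            "synonymous": 0.3,
            "nonsynonymous": 0.3,
            "stop_gain": 0.2,
            "start_loss": 0.1,
            "stop_loss": 0.1,
        },
    )
    genome, genes, variants, expression, truth = simulate(cfg)
    return cfg, genome, genes, variants, expression, truth
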