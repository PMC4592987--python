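import numpy as np
import pytest

from refprime.expression import SampleMeta, TimeCourseMatrix
from refprime.simulate import GenomeSimSpec, simulate_genome


def make_samples(times, replicates=1, course="c1"):
    return [
        SampleMeta(sample_id=f"{course}_t{t:g}_r{r}", time=float(t), replicate=r, course_id=course)
        for t in times
        for r in range(1, replicates + 1)
    ]


def make_matrix(values, times, replicates=1, course="c1", gene_ids=None, scale="absolute"):
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    return TimeCourseMatrix(
        gene_ids=list(gene_ids),
        samples=make_samples(times, replicates, course),
        values=values,
        scale=scale,
    )


@pytest.fixture(scope="session")
def small_genome(tmp_path_factory):
    """A 12-gene synthetic genome with all three exon classes, written once."""
    d = tmp_path_factory.mktemp("genome")
    fasta, gff = d / "genome.fa", d / "genes.gff3"
    truth = simulate_genome(GenomeSimSpec(n_genes=12, seed=11), fasta, gff)
    return fasta, gff, truth
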