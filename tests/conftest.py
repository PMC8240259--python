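import pytest

from soilvirome import GradientConfig, generate_community
from soilvirome.identify import AnnotatedContig, GeneAnnotation


@pytest.fixture(scope="session")
def small_bundle():
    """A small noiseless synthetic community shared across tests."""
    cfg = GradientConfig(
        n_viral_contigs=60,
        n_bacterial_contigs=12,
        seed=7,
        induction_noise_cv=0.0,
    )
    return generate_community(cfg)


def make_contig(
    n_genes=0,
    n_vpf=0,
    n_ko=0,
    n_pfam=0,
    length=6000,
    category=None,
    contig_id="c1",
):
    """Contig with the first n_vpf/n_ko/n_pfam genes carrying each hit type.

    Hit sets overlap (a gene may carry several namespaces), which the
    decision rules must count independently.
    """
    genes = []
    for k in range(n_genes):
        genes.append(
            GeneAnnotation(
                gene_id=f"{contig_id}_g{k}",
                start=k * 10 + 1,
                end=k * 10 + 5,
                vpf_hit=f"VPF_{k}" if k < n_vpf else None,
                ko_hit=f"K{k:05d}" if k < n_ko else None,
                pfam_hit=f"PF{k:05d}" if k < n_pfam else None,
            )
        )
    return AnnotatedContig(
        contig_id=contig_id,
        length_nt=length,
        genes=tuple(genes),
        virsorter_category=category,
    )
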