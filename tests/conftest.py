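import numpy as np
import pytest

from operonwave.operon_io import (
    GeneRecord,
    GenomeAnnotation,
    PromoterRecord,
    TerminatorRecord,
)
from operonwave.synthetic_data import (
    SyntheticConfig,
    generate_annotation,
    generate_expression,
)


@pytest.fixture()
def tiny_annotation() -> GenomeAnnotation:
    """Three operons (one on the minus strand), 7 genes, 4 TSSs, 1 TTS."""
    genes = [
        GeneRecord("a1", "op1", 1, 100, 400, "+"),
        GeneRecord("a2", "op1", 2, 500, 900, "+"),
        GeneRecord("a3", "op1", 3, 1000, 1500, "+"),
        GeneRecord("b1", "op2", 1, 3600, 4000, "-"),
        GeneRecord("b2", "op2", 2, 3000, 3500, "-"),
        GeneRecord("c1", "op3", 1, 5000, 5600, "+"),
        GeneRecord("d1", None, None, 5800, 5950, "+"),
    ]
    promoters = [
        PromoterRecord("P1", "op1", 80, 1),
        PromoterRecord("P2", "op1", 950, 3),   # internal
        PromoterRecord("P3", "op2", 4050, 1),
        PromoterRecord("P4", "op3", 4950, 1),
    ]
    terminators = [TerminatorRecord(tts_nt=1600, operon_id="op1")]
    return GenomeAnnotation(genes=genes, promoters=promoters, terminators=terminators, genome_length_nt=6000)


@pytest.fixture()
def tiny_annotation_tsv(tmp_path, tiny_annotation):
    from operonwave.operon_io import write_annotation

    path = tmp_path / "annotation.tsv"
    write_annotation(tiny_annotation, path)
    return path


@pytest.fixture(scope="session")
def default_dataset():
    """Shared synthetic genome + expression under the default study conditions."""
    cfg = SyntheticConfig(seed=0)
    ann = generate_annotation(cfg)
    expr = generate_expression(ann, cfg)
    return cfg, ann, expr


def make_expression(gene_lfcs: dict[str, float], condition: str = "stress"):
    import pandas as pd

    return pd.DataFrame(
        dict(
            gene_id=list(gene_lfcs),
            condition_id=condition,
            lfc=list(gene_lfcs.values()),
            p_value=np.nan,
        )
    )
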