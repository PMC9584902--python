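import numpy as np
import pandas as pd
import pytest

from holodev.expression_io import ExpressionMatrix, SampleTable

TOY_OBO = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: A

[Term]
id: GO:0000002
name: B
is_a: GO:0000001

[Term]
id: GO:0000003
name: C
is_a: GO:0000002

[Term]
id: GO:0000004
name: D
is_a: GO:0000001

[Term]
id: GO:0000005
name: E
"""


@pytest.fixture
def toy_obo_path(tmp_path):
    """Five-term ontology: A<-B<-C chain, A<-D, isolated E."""
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return path


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples FPKM matrix, one sample per stage."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [0.0, 1.0, 0.0, 1.0]],
        index=["g1", "g2", "g3"],
        columns=["e1", "l1", "p1", "a1"],
    )
    return ExpressionMatrix(data, scale="fpkm")


@pytest.fixture
def small_samples():
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["e1", "l1", "p1", "a1"],
                "major_stage": ["embryo", "larva", "pupa", "adult"],
                "time_order": [1, 2, 3, 4],
                "sex": ["mixed", "mixed", "mixed", "male"],
                "tissue": ["whole_body"] * 4,
            }
        )
    )


def make_samples(stage_counts, sexes=None):
    """SampleTable with n replicates per stage; sample ids '<stage>_<i>'."""
    rows = []
    order = 0
    for stage in ("embryo", "larva", "pupa", "adult"):
        for i in range(stage_counts.get(stage, 0)):
            order += 1
            sid = f"{stage}_{i + 1}"
            rows.append(
                {
                    "sample_id": sid,
                    "major_stage": stage,
                    "time_order": order,
                    "sex": (sexes or {}).get(sid, "mixed"),
                    "tissue": "whole_body",
                }
            )
    return SampleTable(pd.DataFrame(rows))


def stage_matrix_from(profiles, gene_ids=None):
    """Log-scale genes x 4 matrix with columns embryo/larva/pupa/adult."""
    arr = np.asarray(profiles, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(arr, index=genes, columns=["embryo", "larva", "pupa", "adult"]),
        scale="log",
    )
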