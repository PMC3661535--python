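import io

import pytest

from swepatlas.annotation_core import (
    AnnotationMatrix,
    AnnotationRecord,
    GeneMeta,
    StageAxis,
    SWEP,
    parse_annotations,
    parse_gene_meta,
)

# Hand-built toy screen: 9 expressed + 3 silent genes over 4 structures.
# Expected distances/summaries asserted in the tests were computed by hand
# from the count definitions, independently of the implementation.
TOY_ANNOTATIONS = """\
gene_id\tstructure\tdomain\tstage\tdetected
g01\tliver\t\tHH26\t1
g01\tliver\t\tHH28\t1
g01\tgut\t\tHH26\t1
g01\tgut\t\tHH28\t1
g02\tliver\t\tHH22\t1
g02\tliver\t\tHH26\t1
g02\tliver\t\tHH28\t1
g02\tgut\t\tHH26\t1
g02\tgut\t\tHH28\t1
g03\tliver\t\tHH18\t1
g03\tliver\t\tHH22\t1
g03\tliver\t\tHH26\t1
g03\tliver\t\tHH28\t1
g04\tgut\t\tHH28\t1
g05\theart\t\tHH28\t1
g06\tliver\t\tHH26\t1
g06\tliver\t\tHH28\t1
g06\theart\t\tHH26\t1
g06\theart\t\tHH28\t1
g07\teye\t\tHH18\t1
g07\teye\t\tHH22\t1
g08\teye\t\tHH18\t1
g08\teye\t\tHH22\t1
g08\teye\t\tHH26\t1
g09\teye\t\tHH18\t1
g09\teye\t\tHH22\t1
g09\teye\t\tHH26\t1
g09\teye\t\tHH28\t1
g09\tliver\t\tHH18\t1
g09\tliver\t\tHH22\t1
g09\tliver\t\tHH26\t1
g09\tliver\t\tHH28\t1
"""

TOY_GENE_META = """\
gene_id\tgene_class\tcategory
g01\tKinases\ttissue-restricted
g02\tKinases\ttissue-restricted
g03\tKinases\ttissue-restricted
g04\tOthers\ttissue-restricted
g05\tOthers\ttissue-restricted
g06\tOthers\ttissue-restricted
g07\tOthers\ttissue-restricted
g08\tOthers\ttissue-restricted
g09\tOthers\tubiquitous
g10\tKinases\tnot-detected
g11\tOthers\tnot-detected
g12\tOthers\tnot-detected
"""

TOY_PATHWAYS = """\
gene_id\tmajor_category\tspecific_pathway
g01\tcarbohydrate\tcarbohydrate:map010
g02\tcarbohydrate\tcarbohydrate:map020
g02\tlipid\tlipid:map561
g03\tlipid\tlipid:map564
g05\tamino_acid\tamino_acid:map250
g06\tcarbohydrate\tcarbohydrate:map030
"""


@pytest.fixture
def toy_matrix() -> AnnotationMatrix:
    return parse_annotations(
        io.StringIO(TOY_ANNOTATIONS), gene_meta=parse_gene_meta(io.StringIO(TOY_GENE_META))
    )


@pytest.fixture
def toy_annotation_file(tmp_path):
    p = tmp_path / "toy.annotations.tsv"
    p.write_text(TOY_ANNOTATIONS)
    return p


@pytest.fixture
def toy_meta_file(tmp_path):
    p = tmp_path / "toy.gene_meta.tsv"
    p.write_text(TOY_GENE_META)
    return p


@pytest.fixture
def toy_pathway_file(tmp_path):
    p = tmp_path / "toy.pathways.tsv"
    p.write_text(TOY_PATHWAYS)
    return p


def make_matrix(entries, stage_axis=None, gene_meta=None) -> AnnotationMatrix:
    """entries: iterable of (gene, structure, domain, swep-string)."""
    axis = stage_axis or StageAxis()
    records = [
        AnnotationRecord(g, s, d, SWEP.from_string(sw)) for g, s, d, sw in entries
    ]
    return AnnotationMatrix(axis, records, gene_meta)


@pytest.fixture
def make_matrix_fn():
    return make_matrix
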