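import pytest

from onkointerp import fixtures as fx
from onkointerp.harmonize import CancerTypeTable, DrugClassTable
from onkointerp.protein import read_structure


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One deterministic fixture set shared by the whole session."""
    d = tmp_path_factory.mktemp("fixtures")
    fx.generate_toy_kb(seed=1, n_per_source=10, outdir=d / "kb")
    fx.write_cancer_type_table(d / "cancer_types.tsv")
    fx.write_drug_class_table(d / "drug_classes.tsv")
    fx.write_toy_vcf(d / "variants.vcf")
    fx.write_toy_maf(d / "variants.maf")
    keys = [f"{c.removeprefix('chr')}:{p}:{r}:{a}"
            for c, p, _, r, a in fx.TOY_VCF_RECORDS]
    fx.write_toy_annotations(d / "annotations.tsv", keys, seed=1)
    return d


@pytest.fixture(scope="session")
def cancer_table(fixture_dir):
    return CancerTypeTable.from_tsv(fixture_dir / "cancer_types.tsv")


@pytest.fixture(scope="session")
def drug_table(fixture_dir):
    return DrugClassTable.from_tsv(fixture_dir / "drug_classes.tsv")


@pytest.fixture(scope="session")
def helix_model(tmp_path_factory):
    p = tmp_path_factory.mktemp("pdb") / "helix.pdb"
    fx.generate_synthetic_structure("helix", 20, seed=0, path=p)
    return read_structure(p)


@pytest.fixture(scope="session")
def strand_pair_model(tmp_path_factory):
    p = tmp_path_factory.mktemp("pdb") / "strand_pair.pdb"
    fx.generate_synthetic_structure("strand_pair", 16, seed=0, path=p)
    return read_structure(p)


@pytest.fixture(scope="session")
def hairpin_model(tmp_path_factory):
    p = tmp_path_factory.mktemp("pdb") / "hairpin.pdb"
    fx.generate_synthetic_structure("hairpin", 18, seed=0, path=p)
    return read_structure(p)
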