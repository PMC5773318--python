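"""Genotype container and file-format round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from matryoshka import (
    SampleHierarchy,
    SimConfig,
    read_genotypes,
    simulate_hierarchy,
    summarize_missing,
    write_genotypes,
)
from matryoshka.genotypes import GenotypeFormatError, GenotypeValidationError
from matryoshka.simulate import inject_missing

from conftest import make_gm

FORMATS = ["genepop", "structure2row", "csv"]


@st.composite
def random_matrix(draw):
    n = draw(st.integers(2, 8))
    l = draw(st.integers(1, 5))
    alleles = draw(
        st.lists(
            st.lists(st.tuples(st.integers(1, 9), st.integers(1, 9)), min_size=l, max_size=l),
            min_size=n,
            max_size=n,
        )
    )
    arr = np.array(alleles, dtype=np.int32)
    # random missing cells (both slots together)
    miss = draw(st.lists(st.booleans(), min_size=n * l, max_size=n * l))
    arr[np.array(miss).reshape(n, l)] = 0
    if (arr == 0).all(axis=(1, 2)).any():  # keep each individual partly typed
        arr[:, 0, :] = 1
    return make_gm(arr)


@pytest.mark.parametrize("fmt", FORMATS)
@settings(max_examples=25, deadline=None)
@given(gm=random_matrix())
def test_roundtrip_identity(fmt, gm, tmp_path_factory):
    path = tmp_path_factory.mktemp("io") / f"g.{fmt}"
    hier = SampleHierarchy([f"s{i % 2}" if fmt != "genepop" else f"s{i // 5}"
                            for i in range(gm.n_individuals)])
    write_genotypes(gm, hier, path, fmt)
    gm2, _ = read_genotypes(path, fmt)
    assert gm.equals(gm2)


def test_genepop_pop_blocks(tmp_path):
    cfg = SimConfig(seed=2, n_sites=4, n_per_site=20, tree_spec=(2,),
                    missing_rate=0, admixed_fraction=0, hybrid_fraction=0)
    gm, hier, _ = simulate_hierarchy(cfg)
    path = tmp_path / "sites.gen"
    write_genotypes(gm, hier, path, "genepop")
    blocks = sum(1 for ln in path.read_text().splitlines() if ln.strip().lower() == "pop")
    assert blocks == len(set(hier.site))
    gm2, hier2 = read_genotypes(path, "genepop")
    assert len(set(hier2.site)) == 4


def test_structure_missing_code_masks_both_slots(tmp_path):
    path = tmp_path / "s.str"
    path.write_text(
        "L1 L2\n"
        "a 1 3 4\na 1 3 4\n"
        "b 1 0 4\nb 1 0 5\n"
    )
    gm, _ = read_genotypes(path, "structure2row")
    assert gm.missing_mask[1, 0]
    assert tuple(gm.alleles[1, 0]) == (0, 0)
    assert not gm.missing_mask[1, 1]


def test_generator_csv_shape(tmp_path):
    cfg = SimConfig(seed=3, n_sites=1, n_per_site=50, tree_spec=(2,),
                    missing_rate=0, admixed_fraction=0, hybrid_fraction=0)
    gm, hier, _ = simulate_hierarchy(cfg)
    path = tmp_path / "g.csv"
    write_genotypes(gm, hier, path, "csv")
    gm2, _ = read_genotypes(path, "csv")
    assert gm2.n_individuals == 50 and gm2.n_loci == 13
    assert not gm2.missing_mask.any()


def test_half_missing_promoted_to_fully_missing():
    arr = np.array([[[1, 0], [2, 2]], [[1, 1], [2, 2]]])
    gm = make_gm(arr)
    assert gm.missing_mask[0, 0]
    assert tuple(gm.alleles[0, 0]) == (0, 0)
    # invariant: no cell with exactly one missing allele survives parsing
    half = (gm.alleles > 0).any(axis=2) & (gm.alleles == 0).any(axis=2)
    assert not half.any()


def test_summarize_missing_rates():
    arr = np.ones((3, 13, 2), dtype=np.int32)
    arr[1, :5, :] = 0
    gm = make_gm(arr)
    per_ind, per_locus = summarize_missing(gm)
    assert per_ind.iloc[0] == 0
    assert per_ind.iloc[1] == pytest.approx(5 / 13)
    assert per_locus.iloc[0] == pytest.approx(1 / 3)


def test_injected_missing_rate_matches_binomial():
    gm = make_gm(np.ones((1000, 13, 2), dtype=np.int32))
    gm2 = inject_missing(gm, 0.20, seed=11)
    per_ind, _ = summarize_missing(gm2)
    assert abs(per_ind.mean() - 0.20) < 0.02


@pytest.mark.parametrize(
    "text,err",
    [
        ("title\nL1\npop\nno-comma 001001\n", "separator"),
        ("title\nL1\npop\nind1 , 00100\n", "diploid code"),
        ("title\nL1\nL2\npop\nind1 , 001001\n", "expected 2 loci"),
    ],
)
def test_genepop_parse_errors(tmp_path, text, err):
    path = tmp_path / "bad.gen"
    path.write_text(text)
    with pytest.raises(GenotypeFormatError, match=err):
        read_genotypes(path, "genepop")


def test_duplicate_individual_id_rejected():
    with pytest.raises(GenotypeValidationError, match="duplicate"):
        make_gm(np.ones((2, 1, 2), dtype=np.int32), ids=["a", "a"])


def test_write_refuses_zero_loci(tmp_path):
    gm = make_gm(np.ones((2, 1, 2), dtype=np.int32))
    gm.alleles = gm.alleles[:, :0, :]  # degrade after construction
    with pytest.raises(Exception):
        write_genotypes(gm, SampleHierarchy(["s", "s"]), tmp_path / "x.gen", "genepop")


def test_genepop_three_digit_limit(tmp_path):
    gm = make_gm(np.full((2, 1, 2), 1234, dtype=np.int32))
    with pytest.raises(GenotypeFormatError, match="3 digits"):
        write_genotypes(gm, SampleHierarchy(["s", "s"]), tmp_path / "x.gen", "genepop")


def test_hierarchy_must_be_functional_mapping():
    with pytest.raises(GenotypeValidationError, match="two different"):
        SampleHierarchy(["s1", "s1"], island=["a", "b"])
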