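"""Metadata joins: key precedence, taxonomies, drop accounting."""

import io

import pandas as pd
import pytest

import labiofreq as lf
from labiofreq.metadata import MetadataError, load_metadata


def _profiles():
    return pd.DataFrame({
        "doculect_id": ["d1", "d2", "d3"],
        "iso_code": ["aaa", "bbb", "ccc"],
        "glottocode": ["glt1", "glt2", "glt3"],
        "n_consonants": [100, 100, 100],
        "n_labiodental": [5, 0, 2],
        "n_wi_labiodental": [2, 0, 0],
        "lr": [0.05, 0.0, 0.02],
        "wilr": [0.02, 0.0, 0.0],
    })


def _meta(**overrides):
    base = pd.DataFrame({
        "glottocode": ["glt1", "glt2", "glt3"],
        "iso_code": ["aaa", "bbb", "ccc"],
        "lineage": ["F1", "F1", "F2"],
        "region": ["R1", "R2", "R1"],
        "subsistence_large": ["HG", "nonHG", "nonHG"],
        "subsistence_autotyp": ["HG", "", "nonHG"],
    })
    for col, vals in overrides.items():
        base[col] = vals
    return base


def test_full_join_admits_all_rows():
    table = lf.join_metadata(_profiles(), _meta(), taxonomy="large")
    assert table.n == 3
    assert table.frame["hg"].tolist() == [1, 0, 0]
    assert set(table.drop_counts.values()) == {0}
    # transformed columns use the admitted row count for smoothing
    assert table.frame["lr_t"].notna().all()


def test_missing_region_dropped_and_counted():
    table = lf.join_metadata(_profiles(), _meta(region=["R1", "", "R1"]))
    assert table.n == 2
    assert table.drop_counts["no_region"] == 1


def test_autotyp_taxonomy_drops_unassessed():
    table = lf.join_metadata(_profiles(), _meta(), taxonomy="autotyp")
    assert table.n == 2
    assert table.drop_counts["no_subsistence"] == 1
    assert sorted(table.frame["doculect_id"]) == ["d1", "d3"]


def test_large_taxonomy_defaults_absent_label_to_nonhg():
    table = lf.join_metadata(_profiles(), _meta(subsistence_large=["HG", "", ""]))
    assert table.frame["hg"].tolist() == [1, 0, 0]


def test_glottocode_takes_precedence_over_iso():
    meta = _meta()
    # iso 'aaa' points at a different metadata row than glottocode 'glt1'
    meta.loc[0, "iso_code"] = "zzz"
    meta.loc[1, "iso_code"] = "aaa"
    table = lf.join_metadata(_profiles(), meta)
    d1 = table.frame[table.frame.doculect_id == "d1"].iloc[0]
    assert d1.region == "R1"  # matched via glottocode, not iso


def test_iso_fallback_when_glottocode_unknown():
    profiles = _profiles()
    profiles.loc[0, "glottocode"] = "unknown"
    table = lf.join_metadata(profiles, _meta())
    assert table.n == 3


def test_unmatched_profile_dropped():
    profiles = _profiles()
    profiles.loc[2, ["iso_code", "glottocode"]] = ["zzz", "none"]
    table = lf.join_metadata(profiles, _meta())
    assert table.n == 2
    assert table.drop_counts["no_metadata"] == 1


def test_ambiguous_key_is_error():
    meta = _meta(glottocode=["glt1", "glt1", "glt3"])
    with pytest.raises(MetadataError, match="ambiguous"):
        lf.join_metadata(_profiles(), meta)


def test_taxonomy_swap_changes_only_membership_and_indicator():
    large = lf.join_metadata(_profiles(), _meta(), taxonomy="large")
    auto = lf.join_metadata(_profiles(), _meta(), taxonomy="autotyp")
    merged = large.frame.merge(auto.frame, on="doculect_id", suffixes=("_l", "_a"))
    assert (merged["lr_l"] == merged["lr_a"]).all()
    assert (merged["wilr_l"] == merged["wilr_a"]).all()
    assert auto.n <= large.n


def test_presence_indicator_thresholds():
    table = lf.join_metadata(_profiles(), _meta())
    frame = lf.presence_indicator(table)
    assert frame.set_index("doculect_id")["has_labiodental"].to_dict() == {
        "d1": 1, "d2": 0, "d3": 1}


def test_load_metadata_validates_schema_and_labels():
    with pytest.raises(MetadataError, match="glottocode or iso_code"):
        load_metadata(io.StringIO("lineage,region\nF1,R1\n"))
    with pytest.raises(MetadataError, match="labels"):
        load_metadata(io.StringIO(
            "glottocode,lineage,region,subsistence_large\ng1,F1,R1,maybe\n"))
    with pytest.raises(MetadataError, match="vocabulary"):
        load_metadata(io.StringIO(
            "glottocode,lineage,region\ng1,F1,Rx\n"), region_vocabulary=["R1"])
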