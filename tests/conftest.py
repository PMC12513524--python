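import pytest

from sliex import LipidPanel


@pytest.fixture
def hiit_panels():
    """The published HIIT worked-example pre/post panels (mmol/L)."""
    pre = LipidPanel({"TG": 0.86, "LDL_C": 1.40, "HDL_C": 1.20, "TC": 3.00})
    post = LipidPanel({"TG": 0.80, "LDL_C": 1.30, "HDL_C": 1.30, "TC": 3.00})
    return pre, post


@pytest.fixture
def mict_panels():
    """The published MICT worked-example pre/post panels (mmol/L)."""
    pre = LipidPanel({"TG": 1.10, "LDL_C": 1.30, "HDL_C": 0.86, "TC": 2.70})
    post = LipidPanel({"TG": 1.10, "LDL_C": 1.60, "HDL_C": 1.00, "TC": 3.00})
    return pre, post


@pytest.fixture
def panels_csv(tmp_path):
    """CSV file encoding the two worked-example rows."""
    path = tmp_path / "panels.csv"
    path.write_text(
        "subject_id,arm,unit,tg_pre,tg_post,ldl_pre,ldl_post,"
        "hdl_pre,hdl_post,tc_pre,tc_post\n"
        "S1,HIIT,mmol/L,0.86,0.80,1.40,1.30,1.20,1.30,3.00,3.00\n"
        "S2,MICT,mmol/L,1.10,1.10,1.30,1.60,0.86,1.00,2.70,3.00\n"
    )
    return path
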