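"""Packaged reference data.

`survey_read_summary` returns the published per-sample read-accounting and
subsampling-standardized diversity panel of the South China Sea paired
DNA/RNA survey (two sites, eight depths each; 31 libraries as printed). It
is the arithmetic input for the read-accounting checks: metazoan
percentages recomputed from the read counts, and the column extrema that
fixed the 20,204-read rarefaction depth.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def survey_read_summary() -> pd.DataFrame:
    """Per-sample published summary, indexed by sample id.

    Columns: clean_reads, metazoa_pct, protist_reads, metazoan_otus,
    protist_otus, otus_std, chao1_std, ace_std, shannon_std, simpson_std,
    pd_std.
    """
    src = resources.files("microeuk.data").joinpath("south_china_sea_read_summary.tsv")
    with resources.as_file(src) as path:
        df = pd.read_csv(path, sep="\t", comment="#", index_col="sample")
    return df
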