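"""Packaged reference tables.

``load_vus_table`` returns the curated set of 14 blood-RNA-validated
splice-altering VUSs with their published SpliceAI delta scores and the
splicing tools that detected each event. It is used to validate the
SpliceAI thresholding step and the tool-sensitivity bookkeeping against
known outcomes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from splicedx.variants import SpliceAIScores

TOOLS = ("rMATS", "MAJIQ", "FRASER2", "LeafCutterMD")


def load_vus_table() -> pd.DataFrame:
    """The curated VUS reference table as a DataFrame.

    Columns: gene, variant, ds_ag, ds_al, ds_dg, ds_dl, observed_class,
    tools (semicolon-separated tool names, "none" when no tool detected
    the event).
    """
    ref = resources.files("splicedx.data") / "vus_spliceai_table.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def spliceai_scores_of(row) -> SpliceAIScores:
    """SpliceAIScores for one row of the VUS table."""
    return SpliceAIScores(
        ds_ag=float(row.ds_ag), ds_al=float(row.ds_al),
        ds_dg=float(row.ds_dg), ds_dl=float(row.ds_dl),
    )


def tool_detection_tally(table: pd.DataFrame) -> dict:
    """Per-tool detection bookkeeping over the VUS table.

    Returns {"detected": {tool: n}, "solely": {tool: n}, "none": n,
    "sensitivity": {tool: fraction}} where "solely" counts events detected
    by exactly one tool.
    """
    detected = {t: 0 for t in TOOLS}
    solely = {t: 0 for t in TOOLS}
    n_none = 0
    for tools_str in table["tools"]:
        tools = [] if tools_str == "none" else tools_str.split(";")
        if not tools:
            n_none += 1
            continue
        for t in tools:
            detected[t] += 1
        if len(tools) == 1:
            solely[tools[0]] += 1
    n = len(table)
    return {
        "detected": detected,
        "solely": solely,
        "none": n_none,
        "sensitivity": {t: detected[t] / n for t in TOOLS},
        "n_events": n,
    }
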