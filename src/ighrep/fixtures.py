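"""Packaged reference data.

The expanded-clone table transcribes the published characteristics of the
CLL/SLL clones isolated from the double-transgenic mice: per-tissue clone
frequencies, gene calls in both IMGT and VBASE2 nomenclature, corrected SHM
percentages with UM/M status, and the anchor-stripped HCDR3 amino-acid
sequences with their printed lengths and isoelectric points.  It carries no
nucleotide sequences, so it exercises the dedup, feature, stereotypy and
usage stages (pre-annotated mode), not alignment.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_NUMERIC = {"shm_percent": float, "colony_count": int, "total_colonies": int,
            "cdr3_length": int, "pi_printed": float}


def load_expanded_clone_table() -> pd.DataFrame:
    """Load the transcribed expanded CLL/SLL clone table.

    Returns one row per (mouse, tissue, clone) observation, F1
    allotransplant recipients included; ``v_call`` is the VBASE2 gene name
    where known, falling back to the IMGT name.
    """
    with resources.files("ighrep.data").joinpath("expanded_clones.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t", dtype=str)
    for col, dtype in _NUMERIC.items():
        frame[col] = frame[col].astype(dtype)
    frame["is_allotransplant"] = frame["is_allotransplant"] == "true"
    frame["parental_mouse_id"] = frame["parental_mouse_id"].fillna("")
    frame["v_call"] = frame["v_call_vbase2"].where(
        frame["v_call_vbase2"] != "Unknown", frame["v_call_imgt"])
    frame["d_call"] = frame["d_call"].fillna("")
    frame["genotype"] = "+/+"
    return frame
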