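"""Batch workflow: a folder of PAE JSON files to a scored report.

Writes five synthetic proteins as ColabFold-style PAE JSON plus their
ground-truth chopping TSV, segments the whole folder, and evaluates the
predictions — the same pipeline the `paeseg segment` / `paeseg eval`
commands run from the shell.  Prints the aggregate mean +/- SD of IoU and
DBD over the five proteins.
"""

import csv
import tempfile
from pathlib import Path

from paeseg import random_architecture, write_fixture_set
from paeseg.cli import run_eval, run_segment

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    archs = [random_architecture(seed) for seed in range(30, 35)]
    write_fixture_set(tmp / "pae", archs)

    assert run_segment(tmp / "pae", tmp / "predicted.tsv") == 0
    assert run_eval(tmp / "predicted.tsv", tmp / "pae" / "ground_truth.tsv",
                    tmp / "report.tsv") == 0

    with open(tmp / "report.tsv", newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    mean = next(r for r in rows if r["protein_id"] == "#mean")
    sd = next(r for r in rows if r["protein_id"] == "#sd")
    print(f"proteins scored : {len(rows) - 2}")
    print(f"IoU  = {mean['iou']} +/- {sd['iou']}")
    print(f"DBD  = {mean['dbd']} +/- {sd['dbd']}")
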