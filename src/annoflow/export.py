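"""Export a comparison report as a re-executable code + data bundle.

Every figure the tool produces can be exported as plain-text code plus the
CSV/JSON data behind it, so any result can be regenerated (and tweaked)
outside the tool.  The bundle contains:

* the report's data files (``bars.csv``, ``umap_*.csv``, ``panel.csv``,
  ``params.json``) copied verbatim;
* ``regenerate.py`` — a script that recomputes every *derived* artifact from
  the primary data (the rose scaling from the raw bars) and re-renders every
  figure.  Running it inside the bundle directory reproduces the report's
  derived CSVs byte-identically and its figures.
"""

from __future__ import annotations

import shutil
from pathlib import Path

from .errors import ConfigurationError, FormatError

#: files copied verbatim from a report directory into a bundle
_PRIMARY = ["bars.csv", "panel.csv", "params.json"]
#: derived artifacts the regenerate script rebuilds from the primary data
_DERIVED = ["rose.csv"]

_REGENERATE = '''\
"""Regenerate every derived table and figure of an exported comparison report.

Run from inside the bundle directory:  python regenerate.py
Primary data (bars.csv, umap_*.csv, params.json) is read; rose.csv and all
figures are rebuilt from it.
"""
import json
from pathlib import Path

import pandas as pd

from annoflow.compare import rose_scale
from annoflow import plotting

here = Path(__file__).resolve().parent
params = json.loads((here / "params.json").read_text())

bars = pd.read_csv(here / "bars.csv", index_col=0)
rose = rose_scale(bars)
rose.to_csv(here / "rose.csv")

plotting.bars_figure(bars, here / "bars.svg")
plotting.rose_figure(rose, here / "rose.svg")
for umap_csv in sorted(here.glob("umap_*.csv")):
    frame = pd.read_csv(umap_csv)
    modality = umap_csv.stem[len("umap_"):]
    plotting.umap_figure(frame, here / f"umap_{modality}.svg",
                         title=f"UMAP ({modality})")
print("regenerated:", ", ".join(
    p.name for p in sorted(here.glob("*.svg")) + [here / "rose.csv"]))
'''


def export_bundle(report_dir: str | Path, out_dir: str | Path) -> Path:
    """Copy a report's data into ``out_dir`` and write ``regenerate.py``."""
    report_dir = Path(report_dir)
    out_dir = Path(out_dir)
    if not report_dir.is_dir():
        raise FormatError(f"report directory not found: {report_dir}")
    missing = [f for f in _PRIMARY if not (report_dir / f).exists()]
    if missing:
        raise ConfigurationError(
            f"{report_dir} is not a complete report directory; missing: {missing}"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in _PRIMARY:
        shutil.copyfile(report_dir / name, out_dir / name)
    for umap_csv in sorted(report_dir.glob("umap_*.csv")):
        shutil.copyfile(umap_csv, out_dir / umap_csv.name)
    (out_dir / "regenerate.py").write_text(_REGENERATE, encoding="utf-8")
    return out_dir
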