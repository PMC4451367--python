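#!/usr/bin/env python
"""Optional demo: HRV / EEG feature extraction on locally downloaded data.

This script is a convenience wrapper for users who have exported
PhysioNet RR-interval series (one interval in seconds per line) or Bonn
EEG segments (one sample per line) as plain-text files.  No data ship
with the package and nothing is downloaded; if the directories are
absent the script explains what it expects and exits cleanly.

Expected layout (override with --hrv-dir / --eeg-dir):

  data/hrv/healthy/*.txt   data/hrv/chf/*.txt
  data/eeg/H/*.txt         data/eeg/E/*.txt        data/eeg/S/*.txt

Usage:  python scripts/demo_real_data.py [--hrv-dir DIR] [--eeg-dir DIR]
"""

from __future__ import annotations

import argparse
import sys
import warnings
from pathlib import Path

from msekit import eeg_features, group_summary, hrv_features, read_series


def collect(root: Path) -> dict[str, list[Path]]:
    return {
        sub.name: sorted(sub.glob("*.txt"))
        for sub in sorted(p for p in root.iterdir() if p.is_dir())
    }


def run_hrv(root: Path) -> None:
    groups = collect(root)
    feats, labels = [], []
    for label, paths in groups.items():
        for p in paths:
            feats.append(hrv_features(read_series(p), record_id=p.stem))
            labels.append(label)
    if not feats:
        print(f"no HRV records under {root}", file=sys.stderr)
        return
    print("== HRV feature summary (eps* in seconds, fit error in %) ==")
    print(group_summary(feats, labels).to_string())


def run_eeg(root: Path) -> None:
    groups = collect(root)
    feats, labels = [], []
    for label, paths in groups.items():
        for p in paths:
            feats.append(eeg_features(read_series(p), record_id=p.stem))
            labels.append(label)
    if not feats:
        print(f"no EEG records under {root}", file=sys.stderr)
        return
    print("== EEG feature summary (differenced data, eps as SD fraction) ==")
    print(group_summary(feats, labels).to_string())


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--hrv-dir", type=Path, default=Path("data/hrv"))
    ap.add_argument("--eeg-dir", type=Path, default=Path("data/eeg"))
    args = ap.parse_args()

    warnings.simplefilter("ignore")
    any_found = False
    for root, runner in ((args.hrv_dir, run_hrv), (args.eeg_dir, run_eeg)):
        if root.is_dir():
            any_found = True
            runner(root)
        else:
            print(f"directory {root} not found - skipping", file=sys.stderr)
    if not any_found:
        print(__doc__, file=sys.stderr)


if __name__ == "__main__":
    main()
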