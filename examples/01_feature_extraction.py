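"""Extract the nine peak-quality features from a chromatogram export.

Builds a small simulated Skyline-style export (one clean peptide group and
one noise group), writes it to a TSV, reads it back through the parser, and
prints each group's feature vector.
"""

import tempfile
from pathlib import Path

import numpy as np

from peakvote import (
    FEATURE_NAMES,
    SimSpec,
    extract_features,
    read_chromatogram_export,
    simulate_peak_group,
    write_chromatogram_export,
)

spec = SimSpec()
peptide, _ = simulate_peak_group(
    "peptide", spec, np.random.default_rng(1), sequence="ELVISLIVESK"
)
noise, _ = simulate_peak_group(
    "noise", spec, np.random.default_rng(2), morphology="discordant",
    sequence="NOISEPEAKR",
)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "chromatograms.tsv"
    write_chromatogram_export([peptide, noise], path)
    groups = read_chromatogram_export(path)

for group in groups:
    feats = extract_features(group)
    print(f"\n{group.modified_sequence} (charge {group.charge})")
    for name in FEATURE_NAMES:
        print(f"  {name:>20s}: {getattr(feats, name):10.4f}")

print(
    "\nThe peptide group shows co-eluting isotopes (shape similarity near 1,"
    "\nco-elution count 3, jagging 0); the discordant noise group has shifted"
    "\nisotope traces, so its co-elution score is positive and its count < 3."
)
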