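"""Regenerate the packaged synthetic training table.

Produces src/peakvote/data/synthetic_training_table.csv: a simulator-generated
stand-in for a manually annotated 380-peptide / 357-noise training set,
written at a fixed seed with feature values rounded to 6 significant digits.
"""

from pathlib import Path

import pandas as pd

from peakvote import FEATURE_NAMES, SimSpec, simulate_dataset

SEED = 20211203

def main() -> None:
    examples, _ = simulate_dataset(SimSpec(seed=SEED))
    records = []
    for i, ex in enumerate(examples):
        rec = {"source_id": ex.source_id or f"row{i}"}
        rec.update({n: float(f"{getattr(ex.features, n):.6g}") for n in FEATURE_NAMES})
        rec["label"] = ex.annotation
        records.append(rec)
    out = Path(__file__).resolve().parents[1] / "src/peakvote/data/synthetic_training_table.csv"
    pd.DataFrame.from_records(records).to_csv(out, index=False)
    print(f"wrote {out} ({out.stat().st_size} bytes)")

if __name__ == "__main__":
    main()
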