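"""Apply the SDOP quality filter and the study window to the raw fixes.

Fixes with SDOP <= 3 (stationary-test accuracy ~12 m) are retained; the
fraction removed per individual is reported — the study removed 7.1±0.4%
of fixes this way.  Writes results/filtered_fixes.csv.
"""

from pathlib import Path

import pandas as pd

from crocrange import filter_fixes, read_telemetry, tracks

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    telemetry = read_telemetry(ROOT / "sim" / "fixes.csv")
    kept, fracs = [], {}
    for aid, track in tracks(telemetry):
        retained, removed = filter_fixes(track)
        kept.append(retained)
        fracs[aid] = removed
        print(f"{aid}: {len(track)} fixes, removed {removed * 100:.1f}%")
    out = pd.concat(kept, ignore_index=True)
    out.to_csv(ROOT / "filtered_fixes.csv", index=False)
    pooled = sum(fracs.values()) / len(fracs)
    print(f"pooled SDOP removal: {pooled * 100:.2f}% "
          f"(study: 7.1±0.4%); {len(out)} fixes retained")


if __name__ == "__main__":
    main()
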