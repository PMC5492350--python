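#!/usr/bin/env python
"""Materialise the synthetic study inputs as inspectable files.

Writes, under scratch/sim/ (multi-model PDB, CSV — the formats the CLI
consumes): hydrogen-bond trajectories for the four structures, Fe-C30
distance trajectories, lanosterol binding-energy series, a pose set with one
planted near-native pose, and the five transcribed variant-table fixtures.

The downstream analysis scripts (02-05) regenerate the same data in memory
from the same seeds; this script exists so every input can be examined and
fed through the `cyp51var` command line by hand.
"""

import subprocess
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "sim"
SEED = 20070417  # fixed study seed, shared with scripts 02-05


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for preset, extra in (
        ("table5-like", ["--n-frames", "2000"]),
        ("fe-c30", ["--n-frames", "3000"]),
        ("energies", ["--n-frames", "2000"]),
        ("poses", []),
        ("fixtures", []),
    ):
        cmd = [sys.executable, "-m", "cyp51var.cli", "simulate", "--preset", preset,
               "--seed", str(SEED), "--out", str(OUT / preset.replace("-", "_")), *extra]
        subprocess.run(cmd, check=True)
    n_files = sum(1 for _ in OUT.rglob("*") if _.is_file())
    print(f"wrote {n_files} files under {OUT}")


if __name__ == "__main__":
    main()
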