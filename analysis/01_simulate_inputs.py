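#!/usr/bin/env python
"""Generate the synthetic study bundle used by the downstream analysis steps.

Writes FASTA/newick/TSV/CSV inputs plus ground-truth sidecars under
results/simulated/. The stated world: a balanced 8-tip tree whose left half
carries the short (A114/A118) pigment and right half the long (S114/S118)
pigment over an A114/S118 ancestor; one single-species and one clade-level
copy-number gain; 1e6 single-cone reads; a UV-transmitting lens (T50 380 nm).
"""

from pathlib import Path

from uvopsin.simulate import SimulationConfig, simulate_bundle

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main(seed: int = 0) -> None:
    paths = simulate_bundle(OUT, SimulationConfig(seed=seed))
    print(f"wrote {len(paths)} files to {OUT}")
    for name, path in sorted(paths.items()):
        print(f"  {name:16s} {path.name}")


if __name__ == "__main__":
    main()
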