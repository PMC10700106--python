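#!/usr/bin/env python
"""Plaque-screening sample-size design.

How many secondary plaques must be screened to detect, with a chosen
confidence, a phage type present at a given frequency in a lysate? The
detection probability after n plaques is 1 - (1 - p)^n; solving for n at
p = 0.1 and 95% confidence gives the classic "about 28.5, round up to 30"
design used when hunting rare recombinants.

Usage:
    python examples/screening_design.py
"""

from phagemosaic import detection_probability, required_sample_size


def main() -> None:
    design = required_sample_size(p=0.1, confidence=0.95)
    print("minority type at 10%, target confidence 95%:")
    print(f"  exact root n  = {design.n_real:.3f}")
    print(f"  plaques needed = {design.n_int}")
    print(f"  achieved probability at n={design.n_int}: "
          f"{design.achieved_probability:.4f}")
    print(f"  probability if 30 plaques are screened: "
          f"{detection_probability(0.1, 30):.4f}")

    print("\nsample sizes over a design grid (rows: frequency, cols: confidence):")
    confidences = (0.80, 0.90, 0.95, 0.99)
    header = "p \\ c " + "".join(f"{c:>8.0%}" for c in confidences)
    print(header)
    for p in (0.01, 0.05, 0.10, 0.25, 0.50):
        row = "".join(
            f"{required_sample_size(p, c).n_int:>8d}" for c in confidences
        )
        print(f"{p:>5.0%} {row}")


if __name__ == "__main__":
    main()
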