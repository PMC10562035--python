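"""One-time calibration search for the U-Net channel widths.

The reference architecture fixes the *structure* of the dose
prediction network (two 3x3x3 convolutions per level, max-pool 2 encoder,
transposed-convolution k=2 s=2 decoder with concatenation skips, final
1x1x1 projection) and the total trainable parameter count (1,194,857), but
not legibly the per-level channel widths.  This script enumerates standard
variants — doubling progressions and free monotone widths, one or two
convolutions per level, final kernel 1 or 3, several upsampling modes — and
prints every configuration whose parameter total matches the target count
exactly.

Run:  python scripts/calibrate_unet.py [--target 1194857]

The shipped default, channels (21, 37, 167) at depth 2, is the match with
the canonical structure (two convs per level, transposed-conv upsampling,
1x1x1 head); it is verified here by building the real model and counting.
"""

from __future__ import annotations

import argparse
import itertools


def conv(cin: int, cout: int, k: int = 3) -> int:
    return k**3 * cin * cout + cout


def unet_params(channels, enc_convs, dec_convs, up_mode, final_k, cin=4, cout=1) -> int:
    total, prev = 0, cin
    depth = len(channels) - 1
    for lvl in range(depth + 1):
        c = channels[lvl]
        for _ in range(enc_convs):
            total += conv(prev, c)
            prev = c
    for lvl in range(depth - 1, -1, -1):
        c = channels[lvl]
        if up_mode == "tconv2":
            total += 8 * prev * c + c
            prev = 2 * c
        elif up_mode == "tconv3":
            total += 27 * prev * c + c
            prev = 2 * c
        else:  # parameter-free upsampling + concat
            prev = prev + c
        for _ in range(dec_convs):
            total += conv(prev, c)
            prev = c
    return total + conv(prev, cout, final_k)


def search(target: int):
    hits = []
    variants = list(
        itertools.product([1, 2], [1, 2], ["tconv2", "tconv3", "up"], [1, 3])
    )
    # doubling progressions
    for base in range(2, 97):
        for depth in range(1, 5):
            ch = tuple(base * 2**i for i in range(depth + 1))
            for ec, dc, um, fk in variants:
                if unet_params(ch, ec, dc, um, fk) == target:
                    hits.append((ch, ec, dc, um, fk, "doubling"))
    # free monotone widths, depth 2
    for c0 in range(2, 101):
        for c1 in range(c0, 201):
            for c2 in range(c1, 401):
                for ec, dc, um, fk in variants:
                    if um != "tconv2" or (ec, dc) != (2, 2):
                        continue  # canonical decoder family only (fast path)
                    if unet_params((c0, c1, c2), ec, dc, um, fk) == target:
                        hits.append(((c0, c1, c2), ec, dc, um, fk, "free"))
    return hits


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--target", type=int, default=1_194_857)
    args = ap.parse_args()
    hits = search(args.target)
    if not hits:
        print(f"no configuration matches {args.target} parameters")
        return
    for ch, ec, dc, um, fk, family in hits:
        print(
            f"channels {ch} enc_convs {ec} dec_convs {dc} up {um} "
            f"final_kernel {fk} [{family}] -> {args.target}"
        )
    # verify the shipped choice by building the real network
    from protoplan.dose_model import FULL_SCALE_CONFIG, build_unet, count_parameters

    n = count_parameters(build_unet(FULL_SCALE_CONFIG))
    print(f"shipped FULL_SCALE_CONFIG {FULL_SCALE_CONFIG.level_channels}: {n} parameters")


if __name__ == "__main__":
    main()
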