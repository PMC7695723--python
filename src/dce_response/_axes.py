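"""Array-axis conventions shared by the phantom and the segmentation code.

All volumes in this package are indexed ``(si, ap, lr)``:

* axis 0 — superior → inferior (axial slice axis; lower index = superior)
* axis 1 — anterior → posterior (chest wall sits at high indices)
* axis 2 — patient right → patient left (lower index = patient right)
"""

AX_SI = 0
AX_AP = 1
AX_LR = 2

SIDES = ("left", "right")


def lateral_slice(side: str, n_lr: int) -> slice:
    """Index range along the right→left axis covering one lateral half.

    The patient's right occupies low indices; the midline voxel (odd grids)
    goes to the right half.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    mid = n_lr // 2
    return slice(mid, n_lr) if side == "left" else slice(0, mid)


def contralateral(side: str) -> str:
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    return "right" if side == "left" else "left"
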