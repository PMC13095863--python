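"""Independent brute-force oracles shared across test modules."""


def brute_force_call(column, partition):
    """Literal reading of the screening rule: one residue shared by every
    background taxon, a different residue shared by every foreground taxon,
    nothing missing anywhere.  Kept deliberately naive and independent of
    the implementation in diveconv.screen."""
    standard = set("ACDEFGHIKLMNPQRSTVWY")
    bg = [column.get(t) for t in sorted(partition.background)]
    fg = [column.get(t) for t in sorted(partition.foreground)]
    chars = bg + fg
    if any(c is None or c not in standard for c in chars):
        return None
    if len(set(bg)) != 1 or len(set(fg)) != 1:
        return None
    if bg[0] == fg[0]:
        return None
    return bg[0], fg[0]
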