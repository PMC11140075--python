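"""Score one counting table programmatically and compute its RLC.

Emulates the two-key scoring workflow: mark the current cell, advance
to the next, with the no-fungus override available for truly empty
samples.  Prints the per-structure percent root length colonization.
"""

from mycoscore import CountingTable, ScoringSession, apply_entry, compute_rlc

table = CountingTable.empty("A", 1, n_points=10, condition_code="A")
session = ScoringSession(table)

# A stream of keystrokes: at each of 10 points we pass over the six
# structure cells (EH, H, IH, A, V, S); "mark" marks the cell under the
# cursor.  Here points 1-4 get IH, points 1-2 additionally get A.
for point in range(10):
    for structure in ("EH", "H", "IH", "A", "V", "S"):
        if structure == "IH" and point < 4:
            apply_entry(session, "mark")
        if structure == "A" and point < 2:
            apply_entry(session, "mark")
        apply_entry(session, "advance")

print("session complete:", session.complete)
result = compute_rlc(table)
for code, value in result.rlc.items():
    print(f"  {code:>6}: {value:5.1f} %")
# IH was seen at 4 of 10 points (40%), arbuscules at 2 (20%); Total is
# the union of intraradical marks, here identical to IH (40%).
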