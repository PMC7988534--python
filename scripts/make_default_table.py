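"""Regenerate the bundled default square-well parameter table.

Run from the repository root:  python scripts/make_default_table.py
"""

from absheet.model import make_default_table

if __name__ == "__main__":
    table = make_default_table()
    out = "src/absheet/data/default_table.txt"
    table.write(out)
    print(f"wrote {out}: {len(table.pair_well_width)} pair records")
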