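"""Regenerate the shipped surface-class weighting table.

Fits the per-class correction factors against analytic sphere areas (see
``mitoloc.surface.calibrate_surface_table``) and writes the frozen table to
``src/mitoloc/data/surface_class_table.json``.  Deterministic; run from the
repository root after any change to the class enumeration.
"""

from pathlib import Path

from mitoloc.surface import calibrate_surface_table

out = Path(__file__).resolve().parents[1] / "src" / "mitoloc" / "data" / "surface_class_table.json"
out.parent.mkdir(parents=True, exist_ok=True)
table = calibrate_surface_table()
table.to_json(out)
print(f"wrote {out}")
for aniso, err in table.calibration["rms_rel_error"].items():
    print(f"  anisotropy {aniso}: rms relative error {err:.4f}")
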