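"""Unit conversions between the internal pg/mL/min system and
clinically reported units (mg/min secretion, mg/dL concentration)."""

PG_PER_MG = 1e9
ML_PER_DL = 100.0


def pg_per_min_to_mg_per_min(x: float) -> float:
    return x / PG_PER_MG


def pg_per_ml_to_mg_per_dl(x: float) -> float:
    return x * ML_PER_DL / PG_PER_MG


def mg_per_dl_to_pg_per_ml(x: float) -> float:
    return x * PG_PER_MG / ML_PER_DL
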