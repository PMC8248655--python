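import datetime as dt

import pytest

from vesselppp import VesselArrival, VesselType, default_params


def arrival(i, vtype="container", gt=50_000.0, bwd=0.0, port="Oakland",
            date=dt.date(2018, 6, 1), vessel=None, compliant=True, **extra):
    """Compact arrival factory for tests."""
    fields = dict(
        arrival_id=f"A{i:04d}",
        vessel_id=vessel or f"IMO{9000000 + i}",
        vessel_type=vtype,
        bwd_volume=bwd,
        port=port,
        arrival_date=date,
        compliant=compliant,
    )
    code = vtype.value if isinstance(vtype, VesselType) else vtype
    if code in ("atb", "barge_tug"):
        fields.setdefault("precomputed_wsa", extra.pop("barge_wsa", 2500.0))
        fields.setdefault("tug_precomputed_wsa", extra.pop("tug_wsa", 450.0))
    else:
        fields["gross_tonnage"] = gt
    fields.update(extra)
    return VesselArrival(**fields)


@pytest.fixture
def params_table():
    return default_params()


@pytest.fixture
def toy_population():
    """Seven arrivals with easy medians: positive discharges {500, 1000,
    1500} (median 1000); mixed types and tonnages."""
    d = dt.date(2017, 3, 1)
    return [
        arrival(1, "container", gt=40_000, bwd=0.0, date=d),
        arrival(2, "container", gt=55_000, bwd=500.0, date=d),
        arrival(3, "tanker", gt=30_000, bwd=1000.0, date=d),
        arrival(4, "bulker", gt=35_000, bwd=1500.0, date=d),
        arrival(5, "passenger", gt=90_000, bwd=0.0, date=d),
        arrival(6, "roro", gt=55_000, bwd=0.0, date=d),
        arrival(7, "general", gt=9_000, bwd=0.0, date=d),
    ]
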