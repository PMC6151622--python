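"""Benchmark table of 32 protein–protein complexes.

Published reference values for 32 PDB complexes: the computed binding
direction, the sectional contact areas at 1, 3 and 5 Å gap cutoffs, and the
buried 3-D interface area from PISA.  The table ships with the package so
that the cutoff-series decomposition (partial areas and percentage shares)
and the surface/sectional ruggedness ratio can be recomputed and checked
without network access; coordinates themselves are not bundled.
"""

from __future__ import annotations

import io

import pandas as pd

from .areas import AreaSeries, area_ratio

__all__ = ["benchmark_table", "decompose_benchmark", "benchmark_summary"]

# Columns ending in _printed reproduce the published report's own derived
# numbers (ratio, band partial areas, band percentages) exactly as printed;
# they were evidently derived from unrounded areas, so they can differ from
# exact arithmetic on the printed cumulative areas by one unit in the last
# decimal.  The printed partial area of the first band equals area_1A.
_BENCHMARK_TSV = """\
id	x	y	z	area_1A	area_3A	area_5A	surface_area	ratio_printed	partial_1to3A_printed	partial_3to5A_printed	pct_lt1A_printed	pct_1to3A_printed	pct_3to5A_printed
1A19	-0.858840	-0.479551	-0.180066	44.1	179.2	269.4	501.9	1.9	135.2	90.1	16.4	50.2	33.4
1A52	-0.294080	-0.000000	-0.955781	109.9	371.8	607.5	1534.4	2.5	261.9	235.7	18.1	43.1	38.8
1AY7	0.463474	0.674404	-0.574779	68.7	187.1	272	616.9	2.3	118.4	84.9	25.3	43.5	31.2
1BUC	0.330109	0.130558	0.934870	111.2	366.8	473.2	1884.5	4	255.5	106.4	23.5	54.0	22.5
1DEH	0.280917	-0.486684	-0.827179	88.8	302.3	461.4	1647.3	3.6	213.6	159.1	19.2	46.3	34.5
1GLP	0.577662	0.641967	0.504168	139.6	398.8	543.6	1279.7	2.4	259.2	144.8	25.7	47.7	26.6
1GLQ	0.582690	0.700540	0.411966	135	391.3	526.9	1281.1	2.4	256.3	135.6	25.6	48.6	25.7
1GSY	0.818358	0.545212	-0.181752	139.2	364.5	515.2	1191.1	2.3	225.4	150.7	27.0	43.7	29.2
1HDX	0.434733	-0.480141	-0.761887	100.4	308.3	439	1577.3	3.6	208	130.7	22.9	47.4	29.8
1HDY	0.350059	-0.606471	-0.713899	114.7	331.2	469	1680.9	3.6	216.5	137.8	24.5	46.2	29.4
1HSZ	-0.440008	0.553178	0.707380	125.1	343.8	496	1671.5	3.4	218.8	152.2	25.2	44.1	30.7
1HTB	0.370719	-0.642265	-0.670867	119.1	335.8	477.4	1655.9	3.5	216.8	141.6	24.9	45.4	29.7
1U3V	-0.369964	0.502553	0.781388	121.5	327.6	473.5	1612.7	3.4	206	145.9	25.7	43.5	30.8
2BJ4	-0.412982	-0.097308	-0.905526	157.5	323.3	482.1	1506.6	3.1	165.8	158.8	32.7	34.4	32.9
2GLR	0.603841	0.564992	0.562281	138.9	400.1	548.7	1279.1	2.3	261.2	148.5	25.3	47.6	27.1
2HXX	0.4322447	0.788672	0.437020	61.7	171.8	268.3	541.9	2	110.2	96.5	23.0	41.1	36.0
2I0J	-0.976684	-0.195474	-0.088755	134.4	361.7	569.9	1534.6	2.7	227.3	208.2	23.6	39.9	36.5
2JFA	-0.162518	-0.939318	0.302110	113.8	325.2	540.3	1536.5	2.8	211.4	215.1	21.1	39.1	39.8
2JIF	0.234259	0.932876	0.273614	130.3	393.4	541.8	1641.9	3	263.1	148.4	24.0	48.6	27.4
2OA7	0.697742	-0.669865	-0.253843	136.6	400.7	545.9	1247.5	2.3	264.1	145.3	25.0	48.4	26.6
2POG	0.537877	-0.842968	-0.009662	130	362.4	610.3	1470.9	2.4	232.5	247.9	21.3	38.1	40.6
2Q70	0.557888	-0.827531	-0.062875	132.5	355.7	599.7	1482.1	2.5	223.3	244	22.1	37.2	40.7
2UZ8	-0.735231	-0.674951	-0.062266	75.3	208.3	298.3	1143.6	3.8	132.9	90.1	25.2	44.6	30.2
3M8N	0.908404	0.416203	0.039722	141.2	341.7	537.5	1414.5	2.6	200.5	195.8	26.3	37.3	36.4
3MPJ	0.958105	-0.034863	0.284287	107.4	318.7	427.8	1860.5	4.3	211.3	109.1	25.1	49.4	25.5
3O76	0.721400	0.533321	0.441758	149	402.7	552.3	1226.5	2.2	253.7	149.6	27.0	45.9	27.1
4BL7	0.173459	-0.233176	-0.956839	128.2	334.7	514.5	1261.4	2.5	206.5	179.8	24.9	40.1	34.9
4BVX	-0.169235	0.268273	-0.948362	122.9	307.8	473.5	1224.5	2.6	184.9	165.7	26.0	39.0	35.0
4BVY	0.447971	0.227383	0.864650	121.7	311.4	468.6	1211.9	2.6	189.8	157.2	26.0	40.5	33.5
4L1F	0.637533	-0.323275	0.699318	151.1	396.5	550.1	1667.9	3	245.4	153.6	27.5	44.6	27.9
4M9A	-0.351462	0.830645	-0.431860	143.6	387.7	575.2	1632.1	2.8	244.1	187.6	25.0	42.4	32.6
4N5F	0.681050	0.648964	0.339142	105.6	365.1	553.7	1325.9	2.4	259.4	188.7	19.1	46.8	34.1
"""

_CUTOFFS = (1.0, 3.0, 5.0)


def benchmark_table() -> pd.DataFrame:
    """The 32-complex reference table as a DataFrame (areas in Å²)."""
    return pd.read_csv(io.StringIO(_BENCHMARK_TSV), sep="\t")


def decompose_benchmark(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute partial areas, percentage shares and ruggedness ratios.

    Runs the package's cutoff-series decomposition on the tabulated
    cumulative areas and the surface/sectional ratio on the tabulated PISA
    areas, returning one row per complex with full-precision values.
    """
    if df is None:
        df = benchmark_table()
    rows = []
    for _, rec in df.iterrows():
        series = AreaSeries.from_cumulative(
            _CUTOFFS, (rec.area_1A, rec.area_3A, rec.area_5A))
        rows.append({
            "id": rec["id"],
            "partial_lt1A": series.partial_area[0],
            "partial_1to3A": series.partial_area[1],
            "partial_3to5A": series.partial_area[2],
            "pct_lt1A": series.percentage[0],
            "pct_1to3A": series.percentage[1],
            "pct_3to5A": series.percentage[2],
            "ratio": area_ratio(rec.surface_area, rec.area_5A),
        })
    return pd.DataFrame(rows)


def benchmark_summary() -> dict:
    """Column means and the ruggedness-ratio range over the 32 complexes."""
    df = benchmark_table()
    dec = decompose_benchmark(df)
    ratios_1dp = dec["ratio"].round(1)
    return {
        "n_complexes": len(df),
        "mean_area_1A": float(df.area_1A.mean()),
        "mean_area_3A": float(df.area_3A.mean()),
        "mean_area_5A": float(df.area_5A.mean()),
        "mean_surface_area": float(df.surface_area.mean()),
        "mean_partial_lt1A": float(dec.partial_lt1A.mean()),
        "mean_partial_1to3A": float(dec.partial_1to3A.mean()),
        "mean_partial_3to5A": float(dec.partial_3to5A.mean()),
        "mean_pct_lt1A": float(dec.pct_lt1A.mean()),
        "mean_pct_1to3A": float(dec.pct_1to3A.mean()),
        "mean_pct_3to5A": float(dec.pct_3to5A.mean()),
        "mean_ratio": float(ratios_1dp.mean()),
        "ratio_min": float(ratios_1dp.min()),
        "ratio_max": float(ratios_1dp.max()),
    }
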