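"""Pipeline orchestration: simulate -> classify -> geolocate -> altitude ->
metrics -> biomes -> fit, with every intermediate written as a commented CSV
and a JSON manifest listing all artifacts.

All randomness derives from one root seed via named substreams (per
individual, per module), so a re-run with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, activity, biomes, geolocation as geo, gpsmetrics, io, isa, solar, synthetic as syn
from .mixedmodels import (
    BinomialRandomInterceptModel,
    GaussianMixedModel,
    ZeroInflatedMixedModel,
    build_model_frame,
    contrasts_table,
    likelihood_ratio_test,
    tukey_contrasts,
)
from .rasters import write_ascii_grid

STAGES = ("simulate", "classify", "geolocate", "altitude", "metrics", "biomes", "fit")


@dataclass
class PipelineConfig:
    """Run configuration; defaults are the package's reference scenario."""

    output_dir: str = "nocmig_output"
    seed: int = 0
    n_individuals: int = 3
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    calibration_zenith: float = 96.0  # zenith of the synthetic light threshold
    calibration_days: int = 25
    mcmc: dict = field(default_factory=dict)  # McmcSchedule overrides
    min_daily_km: float = 25.0
    raster_extent: tuple = (-20.0, 45.0, -35.0, 60.0)
    raster_cell_deg: float = 0.5
    ocean_rects: tuple = ()
    category_map: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for tup_key in ("raster_extent", "ocean_rects"):
            if tup_key in raw and raw[tup_key] is not None:
                raw[tup_key] = tuple(
                    tuple(x) if isinstance(x, (list, tuple)) else x for x in raw[tup_key]
                )
        return cls(**raw)

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("output_dir", None)  # where results go does not change them
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def sim_config(self, individual: int) -> syn.SimulationConfig:
        kwargs = dict(self.simulation)
        kwargs.setdefault("seed", self.seed * 1000 + individual)
        if "route" in kwargs:
            kwargs["route"] = tuple(tuple(p) for p in kwargs["route"])
        if "stopover_schedule" in kwargs:
            kwargs["stopover_schedule"] = tuple(tuple(p) for p in kwargs["stopover_schedule"])
        return syn.SimulationConfig(**kwargs)


class PipelineRunner:
    """Executes pipeline stages in dependency order, caching intermediates."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.meta = {
            "package": f"nocmig {__version__}",
            "config_hash": config.hash(),
            "seed": config.seed,
        }
        self.artifacts: list[str] = []
        self.cache: dict = {}

    # -- helpers -------------------------------------------------------------

    def _write(self, df: pd.DataFrame, name: str) -> None:
        io.write_csv(df, self.out / name, self.meta)
        self.artifacts.append(name)

    def _ids(self):
        return [f"bird{i:02d}" for i in range(self.config.n_individuals)]

    # -- stages --------------------------------------------------------------

    def simulate(self):
        cfg0 = self.config.sim_config(0)
        west, east, south, north = self.config.raster_extent
        bands = syn.default_band_spec(cfg0, south, north)
        biome_r, dem_r, sea_r = syn.make_rasters(
            self.config.raster_extent, self.config.raster_cell_deg, bands, self.config.ocean_rects
        )
        for name, r in (("biome.asc", biome_r), ("dem.asc", dem_r), ("landsea.asc", sea_r)):
            write_ascii_grid(r, self.out / name)
            self.artifacts.append(name)
        self.cache["rasters"] = (biome_r, dem_r, sea_r)

        tracks, sensors, gps = {}, {}, {}
        for i, ind in enumerate(self._ids()):
            cfg = self.config.sim_config(i)
            track = syn.simulate_track(cfg)
            tracks[ind] = track
            sensors[ind] = syn.simulate_sensor_series(track, cfg)
            gps[ind] = syn.simulate_gps_fixes(track, cfg)
            self._write(track.data, f"true_track_{ind}.csv")
            self._write(sensors[ind].data, f"sensors_{ind}.csv")
            self._write(gps[ind], f"gps_{ind}.csv")
        self.cache.update(tracks=tracks, sensors=sensors, gps=gps)

    def classify(self):
        labels, bouts = {}, {}
        for i, ind in enumerate(self._ids()):
            series = self.cache["sensors"][ind]
            lab = activity.classify_activity(series)
            b = activity.detect_flight_bouts(lab)
            lab = activity.derive_binary_variables(lab, b)
            labels[ind], bouts[ind] = lab, b
            self._write(lab, f"activity_labels_{ind}.csv")
            self._write(
                pd.DataFrame(
                    [
                        {"start": x.start, "end": x.end, "n_intervals": x.n_intervals,
                         "duration_min": x.duration_min}
                        for x in b
                    ]
                ),
                f"flight_bouts_{ind}.csv",
            )
        self.cache.update(labels=labels, bouts=bouts)

    def geolocate(self):
        _, _, sea_r = self.cache["rasters"]
        positions, daily, stopovers, calibrations = {}, {}, {}, {}
        for i, ind in enumerate(self._ids()):
            cfg = self.config.sim_config(i)
            series = self.cache["sensors"][ind]
            thr = syn.light_threshold_for_zenith(self.config.calibration_zenith, cfg)
            tw = geo.detect_twilights(series, thr)
            self._write(tw, f"twilights_{ind}.csv")

            dates = pd.to_datetime(tw["date"])
            cal_tw = tw[dates >= dates.max() - pd.Timedelta(days=self.config.calibration_days - 1)]
            cal = geo.hill_ekstrom_calibrate(
                cal_tw.reset_index(drop=True), lat_hint=cfg.route[-1][1]
            )
            calibrations[ind] = cal
            pos0 = geo.threshold_positions(tw, cal.zenith_effective_deg, lat_hint=cfg.route[0][1])

            # wintering starts after the last flight bout; stopover nights and
            # the wintering period share grouped location parameters
            bouts = self.cache["bouts"][ind]
            arrival = max((b.end for b in bouts), default=None)
            groups = geo.day_roost_groups(tw)
            ev_time = pd.to_datetime(tw.loc[~tw["excluded"], "time"]).reset_index(drop=True)
            if arrival is not None:
                wintering = (ev_time > pd.Timestamp(arrival)).to_numpy()
                if wintering.any():
                    groups[wintering] = groups[wintering][0]

            priors = geo.EstellePriors(
                deployment=cfg.route[0],
                twilight_error=cal,
                land_mask=sea_r,
            )
            schedule = geo.McmcSchedule(**self.config.mcmc)
            refined, _samples = geo.refine_positions_mcmc(
                pos0, priors, tw, group_ids=groups,
                schedule=schedule, rng=np.random.default_rng([self.config.seed % (2**31), 7, i]),
            )
            positions[ind] = refined
            self._write(refined, f"positions_{ind}.csv")
            dd = geo.daily_positions(refined)
            daily[ind] = dd
            self._write(dd, f"daily_positions_{ind}.csv")
            io.write_geojson_track(
                dd["lon"], dd["lat"], self.out / f"track_{ind}.geojson", {"individual": ind}
            )
            self.artifacts.append(f"track_{ind}.geojson")

            # stopover delineation from bout-free nights at estimated positions
            span = (dd["date"].min(), dd["date"].max())
            pos_by_date = dd.set_index("date")

            def night_window(d, _p=pos_by_date):
                row = _p.loc[d] if d in _p.index else _p.iloc[-1]
                return solar.night_window(d, float(row["lon"]), float(row["lat"]))

            sts = activity.delineate_stopovers(bouts, span, night_window)
            stopovers[ind] = sts
            self._write(
                pd.DataFrame(
                    [{"start_date": s.start_date, "end_date": s.end_date, "n_days": s.n_days}
                     for s in sts]
                ),
                f"stopovers_{ind}.csv",
            )
        self.cache.update(
            positions=positions, daily_positions=daily, stopovers=stopovers,
            calibrations=calibrations,
        )

    def altitude(self):
        daily_dz = {}
        for ind in self._ids():
            data = self.cache["sensors"][ind].data
            alt = isa.pressure_to_altitude(data["pressure_hpa"].to_numpy())
            out = pd.DataFrame(
                {"timestamp": data["timestamp"], "pressure_hpa": data["pressure_hpa"],
                 "altitude_asl_m": alt}
            )
            self._write(out, f"altitude_{ind}.csv")
            dz = isa.daily_altitude_change(data["timestamp"], alt)
            daily_dz[ind] = dz
            self._write(
                dz.reset_index().rename(columns={"index": "date"}), f"daily_altitude_change_{ind}.csv"
            )
        self.cache["daily_altitude_change"] = daily_dz

    def metrics(self):
        _, dem_r, _ = self.cache["rasters"]
        records = {}
        for ind in self._ids():
            fixes = self.cache["gps"][ind]
            rec = gpsmetrics.daily_travel_speed(fixes)
            rec = gpsmetrics.retain_travel_segments(rec, self.config.min_daily_km)
            rec = gpsmetrics.altitude_above_ground(rec.dropna(subset=["lon"]), dem_r)
            records[ind] = rec
            self._write(rec, f"gps_daily_{ind}.csv")
        self.cache["gps_daily"] = records

    def biomes(self):
        biome_r, _, _ = self.cache["rasters"]
        cmap = self.config.category_map or biomes.DEFAULT_CATEGORY_MAP
        assignments = {}
        for ind in self._ids():
            dd = self.cache["daily_positions"][ind]
            rows = []
            for _, r in dd.iterrows():
                box = (r["lon_lo"], r["lon_hi"], r["lat_lo"], r["lat_hi"])
                z = biomes.zonal_majority(biome_r, box)
                if z is None:
                    continue
                rows.append(
                    {
                        "date": r["date"],
                        "biome_code": z.majority_code,
                        "biome_name": biomes.BIOME_NAMES.get(z.majority_code, "?"),
                        "majority_fraction": z.majority_fraction,
                        "tie": z.tie,
                        "biome_category": biomes.categorize(z.majority_code, cmap),
                    }
                )
            df = pd.DataFrame(rows)
            df = biomes.exclude_singleton_biomes(df)
            assignments[ind] = df
            self._write(df, f"biome_daily_{ind}.csv")

            gd = self.cache["gps_daily"][ind]
            codes = [
                biomes.sample_point(biome_r, lo, la) for lo, la in zip(gd["lon"], gd["lat"])
            ]
            gd = gd.assign(
                biome_code=[c if c is not None else np.nan for c in codes],
                biome_category=[
                    biomes.categorize(int(c), cmap) if c is not None else None for c in codes
                ],
            )
            self.cache["gps_daily"][ind] = gd
            self._write(gd, f"gps_daily_biomes_{ind}.csv")
        self.cache["biome_daily"] = assignments

    def fit(self):
        frames = []
        for ind in self._ids():
            lab = self.cache["labels"][ind].copy()
            lab["individual_id"] = ind
            dd = self.cache["daily_positions"][ind].set_index("date")
            bio = self.cache["biome_daily"][ind].set_index("date")
            t = pd.to_datetime(lab["timestamp"])
            night_date = (t - pd.Timedelta(hours=12)).dt.date
            lab["date"] = night_date
            lon = night_date.map(lambda d: dd["lon"].get(d, np.nan)).to_numpy(dtype=float)
            lat = night_date.map(lambda d: dd["lat"].get(d, np.nan)).to_numpy(dtype=float)
            ok = np.isfinite(lon)
            lab = lab[ok].reset_index(drop=True)
            lab["period"] = solar.classify_period(
                lab["timestamp"].to_numpy(), lon[ok], lat[ok]
            )
            lab["biome_category"] = lab["date"].map(
                lambda d: bio["biome_category"].get(d, None)
            )
            frames.append(lab)
        records = pd.concat(frames, ignore_index=True)
        stopover_dates = {
            ind: {
                d
                for s in self.cache["stopovers"][ind]
                for d in pd.date_range(s.start_date, s.end_date).date
            }
            for ind in self._ids()
        }

        tables = {}
        for outcome in ("migrating", "foraging"):
            frame = build_model_frame(records, outcome=outcome, stopover_dates=stopover_dates)
            self._write(frame, f"model_frame_{outcome}.csv")
            model = BinomialRandomInterceptModel.from_frame(frame)
            fit = model.fit()
            cons = tukey_contrasts(fit)
            tables[outcome] = (fit, cons)
            self._write(
                pd.DataFrame([dataclasses.asdict(c) for c in cons]),
                f"contrasts_{outcome}.csv",
            )

        # daily-scale models: altitude change (multi-sensor) and GPS speed/AGL
        dz_rows = []
        for ind in self._ids():
            dz = self.cache["daily_altitude_change"][ind]
            bio = self.cache["biome_daily"][ind].set_index("date")
            sts = {
                d
                for s in self.cache["stopovers"][ind]
                for d in pd.date_range(s.start_date, s.end_date).date
            }
            for d, v in dz.items():
                dt = d.date() if hasattr(d, "date") else d
                cat = bio["biome_category"].get(dt, None)
                if cat is None or not np.isfinite(v) or dt in sts:
                    continue
                dz_rows.append(
                    {"individual_id": ind, "date": dt, "outcome": v,
                     "biome_category": cat, "period": "night"}
                )
        dz_frame = pd.DataFrame(dz_rows)
        speed_rows, agl_rows = [], []
        for ind in self._ids():
            gd = self.cache["gps_daily"][ind]
            gd = gd[gd["in_travel_segment"] & gd["biome_category"].notna()]
            for _, r in gd.iterrows():
                base = {"individual_id": ind, "date": r["date"],
                        "biome_category": r["biome_category"], "period": "night"}
                speed_rows.append({**base, "outcome": r["speed_km_per_day"]})
                if np.isfinite(r["altitude_agl_m"]):
                    agl_rows.append({**base, "outcome": r["altitude_agl_m"]})
        speed_frame, agl_frame = pd.DataFrame(speed_rows), pd.DataFrame(agl_rows)

        summary_lines = []
        for name, frame, model_cls in (
            ("daily_altitude_change", dz_frame, GaussianMixedModel),
            ("daily_travel_speed", speed_frame, GaussianMixedModel),
            ("flight_altitude_agl", agl_frame, ZeroInflatedMixedModel),
        ):
            if not len(frame) or frame["biome_category"].nunique() < 2:
                summary_lines.append(f"{name}: insufficient data for a category contrast")
                continue
            self._write(frame, f"model_frame_{name}.csv")
            fit = model_cls.from_frame(frame).fit()
            cons = tukey_contrasts(fit, periods=("night",), period_ref="night")
            tables[name] = (fit, cons)
            self._write(
                pd.DataFrame([dataclasses.asdict(c) for c in cons]), f"contrasts_{name}.csv"
            )

        with (self.out / "model_summaries.txt").open("w") as f:
            for k, v in self.meta.items():
                f.write(f"# {k}: {v}\n")
            for name, (fit, cons) in tables.items():
                f.write(f"\n== {name} ==\n{fit.summary()}\n\n{contrasts_table(cons)}\n")
            for line in summary_lines:
                f.write(f"\n{line}\n")
        self.artifacts.append("model_summaries.txt")
        self.cache["tables"] = tables

    # -- driver ----------------------------------------------------------------

    def run(self, stages: tuple[str, ...] = STAGES) -> dict:
        last = max(STAGES.index(s) for s in stages)
        todo = STAGES[: last + 1]
        for stage in todo:
            try:
                getattr(self, stage)()
            except Exception as exc:
                (self.out / "FAILED").write_text(f"stage {stage}: {exc}\n")
                raise
        manifest = {
            **self.meta,
            "stages": list(todo),
            "artifacts": sorted(set(self.artifacts)),
        }
        (self.out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        return manifest


def run(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the pipeline; returns the output manifest."""
    return PipelineRunner(config).run(stages)
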