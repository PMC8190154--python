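{
 "description": "Management logs for the University of Nebraska-Lincoln ENREC AmeriFlux maize sites, 2019 growing season. Rainfall totals in mm; the growing-season value is the within-season subset of the annual total. Irrigation events are (date, depth mm).",
 "sites": {
  "US-Ne1": {
   "latitude": 41.1653,
   "longitude": -96.4766,
   "crop": "continuous maize",
   "sowing_date": "2019-04-19",
   "harvest_date": "2019-11-05",
   "irrigation_type": "automatic center pivot, 90% efficiency",
   "irrigation_events": [
    ["2019-06-13", 6.35],
    ["2019-07-01", 6.35],
    ["2019-07-08", 30.48],
    ["2019-07-15", 30.48],
    ["2019-07-24", 0.4],
    ["2019-07-29", 31.75],
    ["2019-08-09", 31.75]
   ],
   "total_rainfall_mm": 910.97,
   "rainfall_growing_season_mm": 764.92
  },
  "US-Ne2": {
   "latitude": 41.164,
   "longitude": -96.4701,
   "crop": "rotation maize-soybean",
   "sowing_date": "2019-04-23",
   "harvest_date": "2019-11-07",
   "irrigation_type": "center pivot",
   "irrigation_events": [
    ["2019-07-02", 30.48],
    ["2019-07-08", 30.48],
    ["2019-07-15", 30.48],
    ["2019-07-29", 30.48]
   ],
   "total_rainfall_mm": 896.87,
   "rainfall_growing_season_mm": 752.86
  },
  "US-Ne3": {
   "latitude": 41.179,
   "longitude": -96.439,
   "crop": "rotation maize-soybean",
   "sowing_date": "2019-04-24",
   "harvest_date": "2019-11-07",
   "irrigation_type": "rainfed",
   "irrigation_events": [],
   "total_rainfall_mm": 803.6,
   "rainfall_growing_season_mm": 655.9
  }
 }
}
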