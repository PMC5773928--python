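# The 11 reference NOAA ISD airport stations for the continental-US Medfly
# quarantine analysis, ordered by latitude.  pql_end_date is the last start
# date of the reference run design; temperature records run through
# 2017-05-15.
pql_end_date: "2016-01-01"
sites:
  - {callsign: KSFO, name: "SAN FRANCISCO INTERNATIONAL A", state: CA, latitude: 37.620, longitude: -122.365, elevation: 2.4, start_year: 1950}
  - {callsign: KFAT, name: "FRESNO YOSEMITE INTERNATIONAL", state: CA, latitude: 36.780, longitude: -119.719, elevation: 101.5, start_year: 1950}
  - {callsign: KBUR, name: "BURBANK-GLENDALE-PASA ARPT", state: CA, latitude: 34.201, longitude: -118.358, elevation: 236.2, start_year: 1973}
  - {callsign: KLAX, name: "LOS ANGELES INTERNATIONAL AIR", state: CA, latitude: 33.938, longitude: -118.389, elevation: 29.6, start_year: 1950}
  - {callsign: KRIV, name: "MARCH AIR RESERVE BASE", state: CA, latitude: 33.900, longitude: -117.250, elevation: 468.2, start_year: 1950}
  - {callsign: KSAN, name: "SAN DIEGO INTERNATIONAL AIRPO", state: CA, latitude: 32.734, longitude: -117.183, elevation: 4.6, start_year: 1950}
  - {callsign: KJAX, name: "JACKSONVILLE INTERNATIONAL A", state: FL, latitude: 30.495, longitude: -81.694, elevation: 7.9, start_year: 1950}
  - {callsign: KIAH, name: "G BUSH INTERCONTINENTAL AP/HO", state: TX, latitude: 29.980, longitude: -95.360, elevation: 29.0, start_year: 1970}
  - {callsign: KMCO, name: "ORLANDO INTERNATIONAL AIRPORT", state: FL, latitude: 28.434, longitude: -81.325, elevation: 27.4, start_year: 1973}
  - {callsign: KTPA, name: "TAMPA INTERNATIONAL AIRPORT", state: FL, latitude: 27.962, longitude: -82.540, elevation: 5.8, start_year: 1950}
  - {callsign: KMIA, name: "MIAMI INTERNATIONAL AIRPORT", state: FL, latitude: 25.791, longitude: -80.316, elevation: 8.8, start_year: 1950}
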