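label,kind,lon,lat
Karonga Town,malawi_town,33.93,-9.95
Chitipa,malawi_town,33.27,-9.70
Rumphi,malawi_town,33.86,-11.02
Mzuzu,malawi_town,34.02,-11.46
Nkhata Bay,malawi_town,34.30,-11.61
Mzimba,malawi_town,33.60,-11.90
Kasungu,malawi_town,33.48,-13.03
Lilongwe,malawi_town,33.79,-13.98
Zomba,malawi_town,35.33,-15.39
Blantyre,malawi_town,35.01,-15.79
Tanzania,foreign_country,33.95,-9.57
Zambia,foreign_country,32.98,-10.05
Mozambique,foreign_country,35.40,-14.40
Zimbabwe,foreign_country,32.85,-16.45
South Africa,foreign_country,30.90,-22.30
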