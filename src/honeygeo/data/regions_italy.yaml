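# Italian administrative regions -> macro-region lookup.
#
# The Northern set is fixed by the longitudinal-analysis definition (the
# eight regions between the western and eastern Alpine contact zones).
# Sicily and Sardinia are macro-regions of their own.  The Central/South
# split of the remaining peninsular regions follows the standard Italian
# statistical convention and can be edited here if a different grouping
# is preferred.
North:
  - Piedmont
  - Valle d'Aosta
  - Liguria
  - Lombardy
  - Trentino-Alto Adige
  - Veneto
  - Friuli-Venezia Giulia
  - Emilia-Romagna
Central:
  - Tuscany
  - Umbria
  - Marche
  - Lazio
South:
  - Abruzzo
  - Molise
  - Campania
  - Puglia
  - Basilicata
  - Calabria
Sicily:
  - Sicily
Sardinia:
  - Sardinia
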