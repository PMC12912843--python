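year,fp_t,fpp_t,fcci
2002,2592,173957,0.0149
2003,3610,184870,0.0195
2004,5017,130983,0.0383
2005,6926,309105,0.0224
2006,15274,245807,0.0621
2007,20176,142251,0.1418
2008,24340,129996,0.1872
2009,27260,105769,0.2577
2010,30120,197943,0.1522
2011,32069,180573,0.1776
2012,33569,233566,0.1437
2013,39005,154401,0.2526
2014,50500,225917,0.2235
2015,62100,381049,0.1630
2016,70800,205590,0.3444
2017,81200,272255,0.2983
2018,88000,260456,0.3379
2019,93000,328986,0.2827
2020,93000,240334,0.3870
2021,108500,244526,0.4437
2022,114100,264900,0.4307
2023,120300,206540,0.5825
2024,127500,244581,0.5213
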