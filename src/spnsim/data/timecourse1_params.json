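{
 "description": "Reference hit parameter set (timecourse1). Found by the random-parameter screen from the crisp preset (seed 77, record 833); also forms the stripe pattern from the degraded preset (score 0.032 in both cases). Values are the 48 sampled parameters; fixed parameters take their registry defaults.",
 "preset": "degraded",
 "t_end": 1100.0,
 "dt_out": 5.0,
 "score_crisp": 0.03239401624344869,
 "found_by": {
  "preset": "crisp",
  "seed": 77,
  "record": 833
 },
 "sampled_parameters": {
  "H_en": 75.03748384604225,
  "H_EN": 30.88348293394893,
  "H_wg": 29.299330236041165,
  "H_IWG": 25.361066322816225,
  "H_EWG": 36.8485338642746,
  "H_ptc": 26.226233671896182,
  "H_PTC": 19.02653042248994,
  "H_ci": 15.15640944301475,
  "H_CI": 6.753524924884293,
  "H_CN": 6.073651179722633,
  "H_hh": 60.19526898183173,
  "H_HH": 93.02067869327783,
  "H_PH": 26.23486000912813,
  "kappa_WGen": 0.01390324536282509,
  "nu_WGen": 3.0205785992573393,
  "kappa_CNen": 0.006231308991142045,
  "nu_CNen": 1.624953204020204,
  "kappa_CIwg": 0.5200711871483125,
  "nu_CIwg": 7.99548308798086,
  "kappa_CNwg": 0.0013486098242254528,
  "nu_CNwg": 7.387471476231007,
  "kappa_WGwg": 0.696374912591093,
  "nu_WGwg": 8.302274021692659,
  "kappa_CIptc": 0.4435338112673376,
  "nu_CIptc": 3.6161085437192395,
  "kappa_CNptc": 0.42652320262165966,
  "nu_CNptc": 1.1556700810986866,
  "kappa_ENci": 0.5314513543880328,
  "nu_ENci": 7.676618649870744,
  "kappa_PTCCI": 0.001465361759032453,
  "nu_PTCCI": 2.0140153008088886,
  "kappa_ENhh": 0.0069866907449299825,
  "nu_ENhh": 9.4919837063408,
  "kappa_CNhh": 0.02773530026232512,
  "nu_CNhh": 5.730607680760485,
  "alpha_CIwg": 28.241784933590292,
  "alpha_WGwg": 26.482946024482096,
  "C_CI": 0.006954880792874248,
  "k_PTCHH": 43.23230362727529,
  "r_ExoWG": 12.609574913190576,
  "r_EndoWG": 24.679621776917088,
  "r_MxferWG": 0.0013958420209213046,
  "r_LMxferWG": 57.537275495005815,
  "r_LMxferPTC": 0.0036475348394178855,
  "r_LMxferHH": 138.1621577882768,
  "r_LMxferPH": 0.017133091264337832,
  "PTC_0": 370.41976345031816,
  "HH_0": 6.29794562250235
 }
}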