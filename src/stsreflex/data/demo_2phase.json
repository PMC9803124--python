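{
 "controller_type": "2phase",
 "channel_names": [
  "GLU",
  "ILPSO",
  "RF",
  "VAS",
  "HAMS",
  "BFSH",
  "GAS",
  "SOL",
  "TA"
 ],
 "rf_index": 2,
 "thresholds_deg": [
  77.0,
  5.0,
  0.0
 ],
 "vector": [
  3.0,
  0.0,
  0.8442780067711435,
  2.1347453746067018,
  0.21703797503726358,
  0.7567240310975731,
  0.5998072215290221,
  2.105862039757059,
  1.600556319061969,
  1.5,
  1.353031513612649,
  1.061410392635719,
  1.5,
  1.5,
  1.1156468587634356,
  1.0539714633622583,
  0.7529998955943624,
  1.0451406560227414,
  0.29351445505209817,
  0.8140167335578044,
  0.09658178204813953,
  0.1493625968054202,
  0.01,
  0.01,
  0.17848554076933898,
  0.01,
  0.0611015063906341,
  -0.2417376249958348,
  3.0607625634604245,
  2.0,
  -0.5,
  0.5905046829697564,
  0.2201668858444199,
  0.26358521528233214,
  0.5172842820363628,
  0.01,
  0.3311537570022586,
  0.8827415674097665,
  0.7330921416682964,
  0.10062727847548036,
  0.021026168823579883,
  1.4592763045155286,
  -1.6415430013528338,
  -0.11500945431743403,
  1.155400253158298,
  -4.0,
  -0.6695007239145749,
  0.2501132550081415,
  -8.0,
  -8.0,
  2.976234643899317,
  -1.1199738637680974,
  -0.0003785013649635349,
  -0.8146630432012308,
  -5.748034067226406,
  8.0,
  4.0,
  -0.7256449934938964,
  -0.24279941119554604,
  -1.0,
  -1.6789474165853413,
  -0.2754287108258291,
  -4.0,
  4.0,
  -0.36538415319002115,
  0.6980681298448763,
  8.0,
  6.417686776832994,
  -0.3791529034864811,
  -3.887141555874577,
  -0.617360892212987,
  -0.8273256707781725,
  8.0,
  -4.043399653335474,
  -1.325623725770308,
  1.294088890284165,
  0.8133403950740761,
  -0.6783263365917148,
  -5.758293660777586,
  1.5330598909848199,
  1.6992490524937276,
  2.416254674047658,
  -0.4689171097394692,
  0.3729953934761958,
  -7.581796968078714,
  5.956504202008613,
  1.189479731535151,
  4.0,
  -0.12925529445292627,
  -0.20691446712125394,
  -3.3157566809541787,
  -6.4717481048661565,
  1.8058862391441624,
  2.821161186704077,
  0.9773700249367006,
  0.23006038958498198
 ]
}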