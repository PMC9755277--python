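table,variable,category,elasticity,component_cix,contribution,pct
wealth,mother_age_group,20-24,0.0350,0.0352,0.0012,1.02
wealth,mother_age_group,25-29,0.0181,-0.0124,-0.0002,-0.19
wealth,mother_age_group,30-49,0.0177,0.0279,0.0005,0.41
wealth,mother_age_group,Total,,,0.0015,1.24
wealth,mother_education,Primary,0.0829,-0.2753,-0.0228,-18.84
wealth,mother_education,Secondary,0.2045,0.0362,0.0074,6.12
wealth,mother_education,Higher,0.1093,0.4187,0.0457,37.78
wealth,mother_education,Total,,,0.0303,25.06
wealth,wealth_quintile,Poorer,0.0432,-0.3714,-0.0161,-13.25
wealth,wealth_quintile,Middle,0.0279,0.0273,0.0008,0.63
wealth,wealth_quintile,Higher,0.0391,0.4131,0.0161,13.32
wealth,wealth_quintile,Highest,0.0731,0.8079,0.0591,48.77
wealth,wealth_quintile,Total,,,0.0599,49.47
wealth,partner_education,Primary,0.0065,-0.2098,-0.0014,-1.13
wealth,partner_education,Secondary,0.0128,0.1319,0.0017,1.39
wealth,partner_education,Higher,0.0265,0.4330,0.0115,9.49
wealth,partner_education,Total,,,0.0118,9.75
wealth,residence,Urban,0.0084,0.3970,0.0033,2.75
wealth,media_exposure,Yes,-0.03654,-0.3669,0.0134,11.07
wealth,currently_working,Yes,0.0513,-0.1770,-0.0091,-7.50
wealth,postnatal_visited,Yes,0.1327,-0.0610,-0.0081,-6.69
wealth,anc_category,>=4,0.1210,0.2004,0.0242,20.01
wealth,child_sex,Female,0.0362,-0.0059,-0.0002,-0.18
wealth,living_children_category,2,-0.0341,0.0263,-0.0009,-0.74
wealth,living_children_category,>=3,-0.0097,-0.1457,0.0014,1.16
wealth,living_children_category,Total,,,0.0005,0.42
wealth,division,Chittagong,0.0118,0.0685,0.0008,0.67
wealth,division,Dhaka,-0.0025,0.2778,-0.0007,-0.57
wealth,division,Khulna,-0.0044,-0.0041,0.00002,0.02
wealth,division,Mymensingh,0.0068,-0.2348,-0.0016,-1.32
wealth,division,Rajshahi,-0.0044,-0.1066,0.0005,0.38
wealth,division,Rangpur,0.0299,-0.2782,-0.0083,-6.87
wealth,division,Sylhet,-0.0026,-0.0973,0.0003,0.21
wealth,division,Total,,,-0.00898,-7.48
wealth,Explained,,,,0.11852,97.92
wealth,Residual,,,,0.00528,2.08
education,mother_age_group,20-24,0.0345,0.0877,0.0031,2.29
education,mother_age_group,25-29,0.0181,-0.0296,-0.0005,-0.40
education,mother_age_group,30-49,0.0177,-0.1256,-0.0022,-1.65
education,mother_age_group,Total,,,0.0005,0.24
education,mother_education,Primary,0.0829,-0.6059,-0.0502,-37.43
education,mother_education,Secondary,0.2045,0.1528,0.0312,23.28
education,mother_education,Higher,0.1093,0.8206,0.0897,66.83
education,mother_education,Total,,,0.0715,52.68
education,wealth_quintile,Poorer,0.0432,-0.1550,-0.0067,-4.99
education,wealth_quintile,Middle,0.0279,-0.0073,-0.0002,-0.15
education,wealth_quintile,Higher,0.0391,0.1354,0.0053,3.94
education,wealth_quintile,Highest,0.0731,0.3536,0.0259,19.27
education,wealth_quintile,Total,,,0.0243,18.07
education,partner_education,Primary,0.0065,-0.2039,-0.0013,-0.99
education,partner_education,Secondary,0.0128,0.0868,0.0011,0.83
education,partner_education,Higher,0.0265,0.5536,0.0147,10.95
education,partner_education,Total,,,0.0145,10.79
education,residence,Urban,0.0084,0.0698,0.0006,0.44
education,media_exposure,Yes,-0.03654,-0.1970,0.0072,5.36
education,currently_working,Yes,0.0513,-0.0822,-0.0042,-3.14
education,postnatal_visited,Yes,0.1327,-0.0357,-0.0047,-3.54
education,anc_category,>=4,0.1210,0.1630,0.0197,14.69
education,child_sex,Female,0.0362,0.0118,0.0004,0.32
education,living_children_category,2,-0.0341,0.0031,-0.0001,-0.08
education,living_children_category,>=3,-0.0097,-0.2619,0.0025,1.88
education,living_children_category,Total,,,0.0024,1.80
education,division,Chittagong,0.0118,0.05,0.0006,0.44
education,division,Dhaka,-0.0025,0.0079,-0.00002,-0.015
education,division,Khulna,-0.0044,0.0484,-0.0002,-0.16
education,division,Mymensingh,0.0068,-0.1035,-0.0007,-0.53
education,division,Rajshahi,-0.0044,0.0081,-0.00004,-0.03
education,division,Rangpur,0.0299,0.0556,0.0017,1.24
education,division,Sylhet,-0.0026,-0.2030,0.0005,0.39
education,division,Total,,,0.00184,1.34
education,Explained,,,,0.13404,99.05
education,Residual,,,,0.00012,0.95
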