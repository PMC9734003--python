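peak,compound,slope,intercept,r,linear_low_mg_ml,linear_high_mg_ml,precision_rsd_pct,repeatability_rsd_pct,stability_rsd_pct,recovery_pct,recovery_rsd_pct
X1,oxypaeoniflorin,1233273.12,46449.80,0.9944,0.056,0.559,0.9,2.0,0.5,96.8,0.4
X2,catechin,213488.20,9856.90,0.9983,0.126,1.255,2.4,0.4,2.5,96.8,1.8
X3,albiflorin,31301.02,3371.21,0.9995,0.371,3.711,2.8,1.8,2.8,97.0,1.5
X4,paeoniflorin,353199.09,4111.98,0.9999,0.512,5.117,3.6,0.7,2.5,99.3,1.4
X5,liquiritin,443973.23,-114367.63,0.9985,0.543,5.430,1.2,1.5,0.8,98.7,1.2
X6,galloylpaeoniflorin,931967.24,12146.77,0.9990,0.050,0.494,2.9,0.2,1.3,109.9,1.7
X7,pentagalloylglucose,3542609.33,9102.26,1.0000,0.069,0.695,1.0,1.4,0.4,101.8,1.9
X8,ononin,937109.60,2791.93,1.0000,0.069,0.692,0.6,3.1,0.3,101.2,0.5
X9,isoliquiritin,1557077.22,3899.99,0.9999,0.061,0.611,0.8,2.1,0.7,108.7,0.5
X10,licochalcone B,1291329.69,338.63,0.9999,0.006,0.063,0.8,2.9,0.4,93.8,0.5
X11,liquiritigenin,132434.69,-1198.43,0.9998,0.100,1.000,0.5,1.7,0.3,107.3,0.4
X12,benzoylpaeoniflorin,1537913.99,1164.36,1.0000,0.009,0.093,2.5,1.5,2.7,104.1,1.1
X16,glycyrrhizic acid,858537.93,3267.07,0.9999,0.389,3.890,0.7,0.4,0.4,97.3,0.1
X18,licochalcone A,137500.90,-5234.42,0.9979,0.063,0.629,0.4,2.1,0.3,105.4,0.6
X19,glabridin,563254.16,431.74,0.9999,0.072,0.720,1.1,3.9,0.6,106.9,0.5
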