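year,live,dom,soil,tec,npp,rh,nep,lulcc,necb,transfer
2001,1804.3,375.9,2643,4823.1,,,,,,
2002,1782.6,371.5,2639.9,4794,136.2,126,10.1,37.5,-27.3,1.8
2003,1783.1,368.7,2634.8,4786.7,155.9,124.7,31.2,37.5,-6.3,2.9
2004,1791,373.2,2628.6,4792.9,165.6,121,44.6,37.3,7.2,3.9
2005,1827.5,379.5,2623.4,4830.4,198.2,119.1,79.1,40.5,38.6,5.1
2006,1826.3,386.4,2621.1,4833.8,168.6,121.1,47.5,43,4.5,6.2
2007,1775.3,387.9,2619.7,4782.9,108.2,121.9,-13.7,36.4,-50.1,7.1
2008,1756.1,382.2,2614.9,4753.3,138.5,118.6,19.9,48.7,-28.7,8.1
2009,1740.9,383,2609.5,4733.4,132.6,116.1,16.4,35.7,-19.2,8.7
2010,1799.3,389.2,2604.4,4793,209.4,109.2,100.1,40,60.1,9.4
2011,1780.7,402.3,2605.5,4788.4,144.4,113.4,31,35.1,-4.1,9.8
2012,1781.7,393.2,2607,4781.9,155.9,123.7,32.2,38.4,-6.2,10.2
2013,1698.3,387.5,2605.4,4691.2,63.7,121.9,-58.2,31.6,-89.8,11.2
2014,1705.5,365,2597.3,4667.8,142.4,127.9,14.5,37,-22.5,12.2
2015,1658.5,376.9,2586.9,4622.3,113.1,120.7,-7.6,37,-44.6,13.1
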