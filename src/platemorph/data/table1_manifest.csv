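population_id,site_name,site_number,species,latitude,longitude,year,patry,n_specimens
Ea-01,"Big Spring, UT",1,E_anna,40.7407,-112.6472,2016,sympatric,10
Ec-01,"Big Spring, UT",1,E_carunculatum,40.7407,-112.6472,2016,sympatric,4
Ec-02,"Big Sandy Creek, MT",2,E_carunculatum,48.4519,-109.9199,2015,sympatric,1
Ea-03,"Creston, MT",3,E_anna,48.2437,-114.1406,1972,sympatric,1
Ea-04,"Dry Sheep Creek, NE",4,E_anna,41.9999,-103.9706,2012,sympatric,1
Ea-05,"Fish Springs Run, CA",5,E_anna,37.0794,-118.2539,1998,sympatric,2
Ea-06,"Grace Coolidge Creek, SD",6,E_anna,43.8072,-103.4502,1969,sympatric,1
Ea-07,"Horseshoe Springs, UT",7,E_anna,40.6203,-112.7099,2016,sympatric,1
Ec-07,"Horseshoe Springs, UT",7,E_carunculatum,40.6203,-112.7099,2016,sympatric,1
Ea-08,"Long Valley Creek, CA",8,E_anna,39.7315,-120.0434,1973,sympatric,5
Ea-09,"Murray Creek, NV",9,E_anna,39.2669,-114.8687,2001,sympatric,1
Ec-10,"Malad River, UT",10,E_carunculatum,41.8652,-112.1692,1983,sympatric,2
Ea-11,"Niwot Ditch, CO",11,E_anna,40.1632,-105.1544,2015,sympatric,2
Ec-11,"Niwot Ditch, CO",11,E_carunculatum,40.1632,-105.1544,2015,sympatric,1
Ea-12,"Pondera Coulee, MT",12,E_anna,48.1892,-111.3268,2015,sympatric,1
Ec-12,"Pondera Coulee, MT",12,E_carunculatum,48.1892,-111.3268,2015,sympatric,1
Ea-13,"Beaver Creek, WY",13,E_anna,42.6417,-108.3475,2015,locally_allopatric,1
Ec-14,"Indian Road Camp, MT",14,E_carunculatum,46.3336,-111.5254,2015,locally_allopatric,4
Ea-15,"Jackson, WY",15,E_anna,43.5363,-110.7629,1971,locally_allopatric,2
Ea-16,"Muddy Creek, MT",16,E_anna,47.9796,-112.1565,2015,locally_allopatric,1
Ec-17,"Strawberry River, UT",17,E_carunculatum,40.1692,-110.4229,2016,locally_allopatric,1
Ec-18,"West Greenbelt, CO",18,E_carunculatum,39.7742,-105.1350,2014,locally_allopatric,9
Ec-19,"Bull Lake, MT",19,E_carunculatum,48.2262,-115.8404,2015,allopatric,1
Ec-20,"Crab Creek, WA",20,E_carunculatum,46.8317,-119.8431,2016,allopatric,20
Ec-21,"Clear Lake, IN",21,E_carunculatum,41.7360,-84.8397,1945,allopatric,1
Ec-22,"Columbia River, WA",22,E_carunculatum,45.83,-122.77,1952,allopatric,2
Ec-23,"Douglas Lake, MI",23,E_carunculatum,45.5606,-84.6741,2016,allopatric,17
Ec-24,"Flathead River, MT",24,E_carunculatum,47.3678,-114.5776,2015,allopatric,4
Ec-25,"Home Lake, CO",25,E_carunculatum,37.5756,-106.0937,2015,allopatric,1
Ec-26,"Little Lake, CA",26,E_carunculatum,35.9490,-117.9023,1967,allopatric,1
Ec-27,"Drumond Island, MI",27,E_carunculatum,46.00,-83.66,2002,allopatric,1
Ec-28,"Snake River, ID",28,E_carunculatum,43.7231,-112.0865,1983,allopatric,2
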